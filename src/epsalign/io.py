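"""File formats: FASTA in, match tables and index persistence out.

Coordinates are 0-based half-open everywhere internally and in TSV/BED
output; the optional GFF rendering is 1-based closed per that standard.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .align import LocalMatch
from .ibf import InterleavedBloomFilter
from .segments import Segment, SegmentStats
from .shapes import parse_shape


class FastaError(ValueError):
    pass


_VALID = set("ACGTN")


def read_fasta(path: str | Path, ambiguous: str = "map") -> list[tuple[str, str]]:
    """Read a (possibly wrapped, CRLF) multi-record FASTA.

    Residues are upper-cased; IUPAC ambiguity codes other than N are mapped
    to N (``ambiguous="map"``) or rejected (``ambiguous="reject"``).  Record
    ids are the first whitespace-delimited token of the header.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            if ambiguous == "reject":
                line = _locate_offending(path, rec.id, bad[0])
                raise FastaError(
                    f"{path}:{line}: record {rec.id!r} contains non-ACGTN "
                    f"residue {bad[0]!r}"
                )
            table = str.maketrans({c: "N" for c in bad})
            seq = seq.translate(table)
        records.append((rec.id, seq))
    return records


def _locate_offending(path: Path, rec_id: str, char: str) -> int:
    """Best-effort line number of the first offending residue of a record."""
    inside = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                inside = line[1:].split()[0] == rec_id if line[1:].split() else False
                continue
            if inside and char in line.upper():
                return lineno
    return 0


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- match tables ------------------------------------------------------------

_MATCH_COLS = ["ref_id", "ref_start", "ref_end", "query_id", "query_start",
               "query_end", "strand", "length", "errors", "score", "evalue"]


def matches_to_frame(matches: Sequence[LocalMatch]) -> pd.DataFrame:
    rows = [dataclasses.asdict(m) for m in matches]
    return pd.DataFrame(rows, columns=_MATCH_COLS)


def write_matches(matches: Sequence[LocalMatch], path: str | Path) -> None:
    matches_to_frame(matches).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")


def read_matches(path: str | Path) -> list[LocalMatch]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        ev = r.get("evalue")
        out.append(
            LocalMatch(
                str(r.ref_id), int(r.ref_start), int(r.ref_end),
                str(r.query_id), int(r.query_start), int(r.query_end),
                str(r.strand), int(r.length), int(r.errors), int(r.score),
                None if pd.isna(ev) else float(ev),
            )
        )
    return out


def write_gff(matches: Sequence[LocalMatch], path: str | Path) -> None:
    """GFF3-style rendering: 1-based closed coordinates on the reference."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in matches:
            attrs = (
                f"ID=match;query={m.query_id};qstart={m.query_start + 1};"
                f"qend={m.query_end};length={m.length};errors={m.errors}"
            )
            score = f"{m.evalue:.3g}" if m.evalue is not None else "."
            fh.write(
                f"{m.ref_id}\tepsalign\tmatch\t{m.ref_start + 1}\t{m.ref_end}\t"
                f"{score}\t{m.strand}\t.\t{attrs}\n"
            )


# -- index persistence -------------------------------------------------------

INDEX_MAGIC = "EPSIDX1"


def save_index(index, path: str | Path) -> None:
    """Persist IBF + segment table + stats + shape as one .npz file."""
    seg_ids = np.array([s.sequence_id for s in index.segments])
    seg_coords = np.array([[s.start, s.end] for s in index.segments])
    stats = np.array(
        [[s.distinct_count, s.window_count, float(s.defined)]
         for s in index.stats]
    )
    np.savez_compressed(
        path,
        magic=np.array(INDEX_MAGIC),
        shape=np.array(str(index.shape)),
        overlap=index.overlap,
        seg_ids=seg_ids,
        seg_coords=seg_coords,
        stats=stats,
        ibf_bin_count=index.ibf.bin_count,
        ibf_bits_per_bin=index.ibf.bits_per_bin,
        ibf_hash_count=index.ibf.hash_count,
        ibf_target_fpr=index.ibf.target_fpr,
        ibf_bits=np.packbits(index.ibf.bits),
    )


def load_index(path: str | Path):
    from .pipeline import ReferenceIndex  # local import to avoid a cycle

    with np.load(path, allow_pickle=False) as z:
        if str(z["magic"]) != INDEX_MAGIC:
            raise ValueError(f"{path}: not an {INDEX_MAGIC} index file")
        shape = parse_shape(str(z["shape"]))
        segs = [
            Segment(str(sid), i, int(c[0]), int(c[1]), "reference")
            for i, (sid, c) in enumerate(zip(z["seg_ids"], z["seg_coords"]))
        ]
        stats = []
        for distinct, windows, defined in z["stats"]:
            if defined < 0.5 or windows < 1:
                stats.append(SegmentStats.undefined())
            else:
                v = float(distinct) / float(windows)
                stats.append(
                    SegmentStats(int(distinct), int(windows), v, 1.0 - v)
                )
        b = int(z["ibf_bin_count"])
        m = int(z["ibf_bits_per_bin"])
        bits = np.unpackbits(z["ibf_bits"])[: m * b].astype(bool)
        ibf = InterleavedBloomFilter(
            b, m, int(z["ibf_hash_count"]), float(z["ibf_target_fpr"]), bits
        )
        return ReferenceIndex(ibf, segs, stats, shape, int(z["overlap"]))


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
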