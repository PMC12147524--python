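"""Strand-aware per-cytosine mutation counting from aligned reads.

A converted f5C site shows up as C-to-T mismatches in reads from the
strand carrying the cytosine.  For a site whose C lies on the reference
'+' strand this is a plain C-to-T mismatch in forward alignments; for a
site whose C lies on the '-' strand the same evidence appears as G-to-A
in reverse-flagged alignments (SAM stores sequences in forward reference
orientation).  The library protocol is assumed strand-preserving, so each
site only counts alignments from its own strand.

Coordinates are 0-based half-open internally; TSV output additionally
carries a 1-based display column.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import revcomp

__all__ = ["build_pileup", "mutation_rate", "load_reference", "write_pileup_tsv"]

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

# counter layout per position/strand: 0 = n_T (mutation evidence),
# 1 = n_C (reference call), 2 = n_other
_EVIDENCE_FWD = {_T: 0, _C: 1}  # at reference C, forward reads
_EVIDENCE_REV = {_A: 0, _G: 1}  # at reference G, reverse reads


class ReferenceMismatchError(ValueError):
    """A SAM reference name is absent from the supplied FASTA."""


def load_reference(ref: dict[str, str] | str | Path) -> dict[str, str]:
    """Accept a {name: sequence} dict or a FASTA path (via pyfaidx)."""
    if isinstance(ref, dict):
        return {k: v.upper().replace("U", "T") for k, v in ref.items()}
    import pyfaidx

    fa = pyfaidx.Fasta(str(ref))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _open_sam(sam: str | Path | pysam.AlignmentFile):
    if isinstance(sam, pysam.AlignmentFile):
        return sam, None
    if isinstance(sam, str) and "\n" in sam:
        # raw SAM text: pysam needs a real file handle
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(sam)
        tmp.close()
        return pysam.AlignmentFile(tmp.name, "r", check_sq=False), tmp.name
    return pysam.AlignmentFile(str(sam), "r", check_sq=False), None


def build_pileup(
    sam: str | Path | pysam.AlignmentFile,
    ref: dict[str, str] | str | Path,
    min_baseq: int = 20,
    min_mapq: int = 10,
    strands: str = "both",
    context_pad: int = 2,
) -> pd.DataFrame:
    """Count per-cytosine C-to-T evidence from a SAM alignment stream.

    Returns one row per reference-strand cytosine with nonzero filtered
    coverage: columns ref, pos0, pos1, strand, context, coverage, n_T,
    n_C, n_other, rate.  Bases below ``min_baseq``, reads below
    ``min_mapq``, read Ns and deletions contribute to no counter.
    ``strands`` restricts output to '+', '-' or 'both'.
    """
    if min_baseq < 0 or min_mapq < 0:
        raise ValueError("quality thresholds must be >= 0")
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    refs = load_reference(ref)
    ref_arr = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for name, seq in refs.items()
    }
    # counts[name][strand_idx] has shape (L, 3)
    counts: dict[str, np.ndarray] = {
        name: np.zeros((2, len(seq), 3), dtype=np.int64) for name, seq in refs.items()
    }

    handle, tmpname = _open_sam(sam)
    try:
        for aln in handle.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            name = aln.reference_name
            if name not in ref_arr:
                raise ReferenceMismatchError(
                    f"read {aln.query_name!r} aligned to {name!r}, "
                    "which is absent from the reference"
                )
            sidx = 1 if aln.is_reverse else 0
            rarr = ref_arr[name]
            want_ref = _G if sidx else _C
            evidence = _EVIDENCE_REV if sidx else _EVIDENCE_FWD
            qseq = aln.query_sequence
            quals = aln.query_qualities
            cigar = aln.cigartuples
            if cigar is None:
                raise ValueError(f"read {aln.query_name!r} has no CIGAR")
            if len(cigar) == 1 and cigar[0][0] == 0:
                # common perfect-match case, vectorized
                start = aln.reference_start
                span = cigar[0][1]
                q = np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)
                qu = np.asarray(quals, dtype=np.int32)
                hit = (rarr[start : start + span] == want_ref) & (qu >= min_baseq)
                pos = np.flatnonzero(hit)
                if pos.size:
                    base = q[pos]
                    cnt = counts[name][sidx]
                    tgt = np.full(pos.size, 2, dtype=np.int64)
                    for b, j in evidence.items():
                        tgt[base == b] = j
                    ok = base != _N
                    np.add.at(cnt, (start + pos[ok], tgt[ok]), 1)
                continue
            cnt = counts[name][sidx]
            for qpos, rpos in aln.get_aligned_pairs(matches_only=False):
                if rpos is None or qpos is None:
                    continue  # insertions/clips have no site; deletions no base
                if rpos >= len(rarr) or rarr[rpos] != want_ref:
                    continue
                if quals[qpos] < min_baseq:
                    continue
                b = ord(qseq[qpos])
                if b == _N:
                    continue
                cnt[rpos, evidence.get(b, 2)] += 1
    finally:
        if tmpname is not None:
            handle.close()
            Path(tmpname).unlink(missing_ok=True)

    rows = []
    for name, seq in refs.items():
        rarr = ref_arr[name]
        for sidx, strand in ((0, "+"), (1, "-")):
            if strands != "both" and strand != strands:
                continue
            cnt = counts[name][sidx]
            cov = cnt.sum(axis=1)
            is_site = rarr == (_G if sidx else _C)
            for pos in np.flatnonzero(is_site & (cov > 0)):
                pos = int(pos)
                lo, hi = max(0, pos - context_pad), pos + context_pad + 1
                ctx = seq[lo:hi]
                if strand == "-":
                    ctx = revcomp(ctx)
                n_t, n_c, n_o = (int(x) for x in cnt[pos])
                rows.append(
                    (
                        name,
                        pos,
                        pos + 1,
                        strand,
                        ctx,
                        int(cov[pos]),
                        n_t,
                        n_c,
                        n_o,
                        n_t / int(cov[pos]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "ref",
            "pos0",
            "pos1",
            "strand",
            "context",
            "coverage",
            "n_T",
            "n_C",
            "n_other",
            "rate",
        ],
    )


def mutation_rate(rec: pd.Series | tuple[int, int]) -> float:
    """C-to-T mutation rate n_T / coverage of one site record."""
    if isinstance(rec, tuple):
        n_t, cov = rec
    else:
        n_t, cov = rec["n_T"], rec["coverage"]
    if cov <= 0:
        raise ValueError("mutation rate undefined at zero coverage")
    return n_t / cov


def write_pileup_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
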