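"""Synthetic f5C-seq library generation.

The generative model mirrors the chemistry of the assay, per RNA molecule:

* a cytosine at a modified site carries f5C with probability ``f`` (the
  site's modification fraction);
* a carried f5C is reduced to dihydrouracil with probability ``eps``
  (the pic-borane conversion efficiency); DHU is read through by reverse
  transcriptase and called T;
* any unconverted cytosine is miscalled T with probability ``e0`` (the
  background C-to-T error), so the expected per-site C-to-T rate is
  ``f*eps + (1 - f*eps)*e0``;
* an optional uniform sequencing error flips any base to one of the other
  three;
* molecules are fragmented at uniform random breakpoints with
  truncated-normal fragment lengths, emulating alkaline fragmentation
  (which leaves the f5C base itself intact).

Three treatment modes are supported.  ``pic_borane`` is the assay proper.
``untreated_input`` is the no-reductant control library (conversion
efficiency forced to zero) used downstream to filter SNPs and native
C-to-U editing.  ``malononitrile`` models the adduct-forming alternative
chemistry whose dominant product is an RT stop: each adducted site
truncates the cDNA with probability ``tau``, so the expected read-through
rate at a single site is ``1 - f*tau``; adducted sites that are read
through are miscoded as T.

Output is an in-memory FASTQ, a "perfect" SAM (true coordinates, no
aligner) and a per-site expected-rate table; a fixed seed makes all three
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SpikeInDesign",
    "SimResult",
    "make_truth_table",
    "enumerate_contexts",
    "spike_in_reference",
    "simulate_library",
    "simulate_rt_stop",
    "simulate_site_counts",
    "expected_ct_rate",
    "random_transcripts",
    "revcomp",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _T, _N = ord("C"), ord("T"), ord("N")
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

MODES = ("pic_borane", "malononitrile", "untreated_input")


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii").upper(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode("ascii")


@dataclass
class SimConfig:
    """Generative parameters of a simulated library.

    ``reads_per_transcript`` fragments are drawn per transcript; the
    realized coverage of a site is the number of fragments spanning it.
    """

    seed: int = 0
    reads_per_transcript: int = 100
    mode: str = "pic_borane"
    conversion_efficiency: float = 0.9
    background_ct_error: float = 0.002
    generic_seq_error: float = 0.0
    fragment_length_mean: float = 40.0
    fragment_length_sd: float = 8.0
    fragment_length_min: int = 15
    rt_stop_prob: float = 0.0
    indel_prob: float = 0.0
    read_prefix: str = "sim"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reads_per_transcript <= 0:
            raise ValueError("reads_per_transcript must be positive")
        for name, val, hi_open in (
            ("conversion_efficiency", self.conversion_efficiency, False),
            ("background_ct_error", self.background_ct_error, True),
            ("generic_seq_error", self.generic_seq_error, True),
            ("rt_stop_prob", self.rt_stop_prob, False),
            ("indel_prob", self.indel_prob, False),
        ):
            ok = 0.0 <= val < 1.0 if hi_open else 0.0 <= val <= 1.0
            if not ok:
                raise ValueError(f"{name} out of range: {val}")

    @property
    def effective_efficiency(self) -> float:
        """Conversion efficiency after accounting for mode (input => 0)."""
        return 0.0 if self.mode == "untreated_input" else self.conversion_efficiency


def expected_ct_rate(f: float, eps: float, e0: float) -> float:
    """Expected C-to-T mutation rate at a site with modification fraction f."""
    return f * eps + (1.0 - f * eps) * e0


def make_truth_table(sites: list[tuple[str, int, str, float]]) -> pd.DataFrame:
    """Build a truth table from (ref, pos0, strand, fraction) tuples."""
    df = pd.DataFrame(sites, columns=["ref", "pos0", "strand", "fraction"])
    if not df.empty:
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].tolist()}")
        if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
    return df


def _validate_truth(ref: dict[str, str], truth: pd.DataFrame) -> None:
    for row in truth.itertuples():
        if row.ref not in ref:
            raise ValueError(f"truth site on unknown reference {row.ref!r}")
        seq = ref[row.ref]
        if not 0 <= row.pos0 < len(seq):
            raise ValueError(f"truth position {row.ref}:{row.pos0} outside reference")
        base = seq[row.pos0].upper()
        want = "C" if row.strand == "+" else "G"
        if base != want:
            raise ValueError(
                f"truth site {row.ref}:{row.pos0}({row.strand}) is {base!r} in the "
                f"reference; a {row.strand}-strand f5C site requires {want!r}"
            )


# ---------------------------------------------------------------------------
# spike-in designs


@dataclass
class SpikeInDesign:
    """A wildcard spike-in motif plus a calibration fraction series.

    ``motif`` uses A/C/G/U plus N wildcards, with the modified cytosine at
    ``anchor`` (default: the unique C in the motif).  Expanding the N
    positions over {A, C, G, U} yields the context oligos (256 for NNCNN);
    ``fractions`` is the series of nominal modification fractions for the
    calibration oligos.
    """

    motif: str = "NNCNN"
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    copies: int = 1
    anchor: int | None = None
    context_fraction: float = 1.0

    def __post_init__(self) -> None:
        motif = self.motif.upper().replace("T", "U")
        if set(motif) - set("ACGUN"):
            raise ValueError(f"motif may contain only A/C/G/U/N, got {self.motif!r}")
        self.motif = motif
        if self.anchor is None:
            anchors = [i for i, b in enumerate(motif) if b == "C"]
            if len(anchors) != 1:
                raise ValueError(
                    "motif must contain exactly one literal C (the modified-C "
                    f"anchor) or an explicit anchor index; got {self.motif!r}"
                )
            self.anchor = anchors[0]
        if not (0 <= self.anchor < len(motif)) or motif[self.anchor] != "C":
            raise ValueError(f"anchor {self.anchor} is not a C in motif {motif!r}")

    @property
    def n_wildcards(self) -> int:
        return self.motif.count("N")


def enumerate_contexts(design: SpikeInDesign) -> list[str]:
    """All distinct wildcard expansions of the motif, lexicographically sorted.

    NNCNN expands to the full 4**4 = 256 five-mer contexts around the
    modified C.
    """
    contexts = [""]
    for base in design.motif:
        opts = "ACGU" if base == "N" else base
        contexts = [c + o for c in contexts for o in opts]
    return sorted(set(contexts))


#: flanks placed around each spike-in context so short-fragment reads exist
_SPIKE_5P = "TAGAGAATTC"
_SPIKE_3P = "GGATCCTCTA"


def spike_in_reference(design: SpikeInDesign) -> tuple[dict[str, str], pd.DataFrame]:
    """Build a reference + truth table realizing a spike-in design.

    Each of the 4**n context oligos is one short transcript with the
    modified C at a fixed offset (nominal fraction ``context_fraction``);
    each calibration fraction is one additional transcript using the
    all-A context.  Sequences are returned in the DNA alphabet.
    """
    ref: dict[str, str] = {}
    rows: list[tuple[str, int, str, float]] = []
    pos = len(_SPIKE_5P) + design.anchor
    for ctx in enumerate_contexts(design):
        name = f"spike_ctx_{ctx}"
        ref[name] = (_SPIKE_5P + ctx + _SPIKE_3P).replace("U", "T")
        rows.append((name, pos, "+", design.context_fraction))
    frac_motif = design.motif.replace("N", "A")
    for i, f in enumerate(design.fractions):
        name = f"spike_frac_{i}"
        ref[name] = (_SPIKE_5P + frac_motif + _SPIKE_3P).replace("U", "T")
        rows.append((name, pos, "+", float(f)))
    return ref, make_truth_table(rows)


def random_transcripts(
    rng: np.random.Generator,
    n: int,
    length: int = 200,
    prefix: str = "tx",
    gc: float = 0.5,
) -> dict[str, str]:
    """Random transcript set with roughly uniform base composition."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"{prefix}{i}": rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
        for i in range(n)
    }


# ---------------------------------------------------------------------------
# read generation


@dataclass
class SimResult:
    """In-memory simulated library plus ground truth."""

    fastq: str
    sam: str
    truth: pd.DataFrame
    expected_rates: pd.DataFrame
    readthrough: pd.DataFrame | None = None

    def write(self, outdir: str | Path, stem: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / f"{stem}.fastq",
            "sam": outdir / f"{stem}.sam",
            "truth": outdir / f"{stem}.truth.tsv",
            "expected": outdir / f"{stem}.expected.tsv",
        }
        paths["fastq"].write_text(self.fastq)
        paths["sam"].write_text(self.sam)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.expected_rates.to_csv(paths["expected"], sep="\t", index=False)
        if self.readthrough is not None:
            paths["readthrough"] = outdir / f"{stem}.readthrough.tsv"
            self.readthrough.to_csv(paths["readthrough"], sep="\t", index=False)
        return paths


def _fragment_coords(
    rng: np.random.Generator, L: int, n: int, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random fragment start coordinates with truncated-normal lengths."""
    lo = min(cfg.fragment_length_min, L)
    lens = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
    lens = np.clip(np.rint(lens).astype(np.int64), lo, L)
    starts = rng.integers(0, L - lens + 1)
    return starts, lens


def _apply_indel(
    rng: np.random.Generator, seq: str, ref_len: int
) -> tuple[str, list[tuple[int, int]]]:
    """Insert or delete 1-2 bases at an interior position.

    Returns the new sequence and a CIGAR as [(oplen, op)] with op in
    'MID'; reference span shrinks by the deletion length.
    """
    k = int(rng.integers(1, 3))
    if rng.random() < 0.5 and len(seq) > k + 2:  # deletion
        pos = int(rng.integers(1, len(seq) - k))
        new = seq[:pos] + seq[pos + k :]
        cig = [(pos, "M"), (k, "D"), (len(seq) - pos - k, "M")]
    else:  # insertion
        pos = int(rng.integers(1, len(seq)))
        ins = rng.choice(_BASES, size=k).tobytes().decode("ascii")
        new = seq[:pos] + ins + seq[pos:]
        cig = [(pos, "M"), (k, "I"), (len(seq) - pos, "M")]
    return new, [(n, op) for n, op in cig if n > 0]


def _cigar_str(cig: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cig)


def simulate_library(
    ref: dict[str, str], truth: pd.DataFrame, cfg: SimConfig
) -> SimResult:
    """Simulate a converted sequencing library over *ref* given *truth*.

    Returns FASTQ text (reads in molecule orientation), SAM text with
    matching names/sequences/coordinates, and the per-site expected
    C-to-T rate table.  Sites on '-' strand transcripts produce G-to-A
    evidence in reference space (reads carry the SAM reverse flag).
    """
    _validate_truth(ref, truth)
    rng = np.random.default_rng(cfg.seed)
    eps = cfg.effective_efficiency
    e0 = cfg.background_ct_error
    rt_mode = cfg.mode == "malononitrile"

    # strand per transcript: a transcript is '-' if any of its truth sites
    # is annotated '-'; mixed-strand truth on one transcript is rejected.
    strand_of: dict[str, str] = {name: "+" for name in ref}
    for name, grp in truth.groupby("ref"):
        strands = set(grp["strand"])
        if len(strands) > 1:
            raise ValueError(f"transcript {name} has truth sites on both strands")
        strand_of[name] = strands.pop()

    fastq_parts: list[str] = []
    sam_body: list[str] = []
    header = ["@HD\tVN:1.6\tSO:unknown"]
    for name, seq in ref.items():
        header.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    rt_rows: list[tuple] = []

    for name, seq in ref.items():
        seq = seq.upper().replace("U", "T")
        L = len(seq)
        strand = strand_of[name]
        molecule = revcomp(seq) if strand == "-" else seq
        mol = np.frombuffer(molecule.encode("ascii"), dtype=np.uint8).copy()
        n = cfg.reads_per_transcript
        starts, lens = _fragment_coords(rng, L, n, cfg)
        ends = starts + lens

        sites = truth[truth["ref"] == name]
        # molecule-space positions of the modified Cs
        mol_pos = [
            (int(p) if strand == "+" else L - 1 - int(p), float(f))
            for p, f in zip(sites["pos0"], sites["fraction"])
        ]

        # RT stops (malononitrile): truncate cDNA 3' of the adduct
        if rt_mode:
            cut = starts.copy()  # molecule-space new start after truncation
            for p, f in mol_pos:
                cover = (starts <= p) & (ends > p)
                idx = np.flatnonzero(cover)
                modified = rng.random(idx.size) < f
                stopped = modified & (rng.random(idx.size) < cfg.rt_stop_prob)
                hit = idx[stopped]
                cut[hit] = np.maximum(cut[hit], p + 1)
                emitted = cover.copy()
                emitted[hit] = False
                ref_pos = int(p if strand == "+" else L - 1 - p)
                rt_rows.append(
                    (name, ref_pos, strand, f, int(cover.sum()), int(emitted.sum()))
                )
            starts = cut
            lens = ends - starts
            keep = lens > 0
            starts, lens, ends = starts[keep], lens[keep], ends[keep]

        n_reads = starts.size
        maxlen = int(lens.max()) if n_reads else 0
        cols = np.arange(maxlen)
        idx = np.minimum(starts[:, None] + cols[None, :], L - 1)
        valid = cols[None, :] < lens[:, None]
        reads = mol[idx]

        # chemical conversion / adduct miscoding at modified sites
        for p, f in mol_pos:
            cover = (starts <= p) & (ends > p)
            rows = np.flatnonzero(cover)
            if rt_mode:
                # surviving spanning reads carry the adduct iff modified and
                # not stopped; read-through adducts are miscalled T
                conv = rng.random(rows.size) < f * (1.0 - cfg.rt_stop_prob)
            else:
                modified = rng.random(rows.size) < f
                conv = modified & (rng.random(rows.size) < eps)
            reads[rows[conv], p - starts[rows[conv]]] = _T

        # background C-to-T miscalls on every remaining cytosine
        if e0 > 0:
            cmask = (reads == _C) & valid
            flips = rng.random(reads.shape) < e0
            reads[cmask & flips] = _T

        # uniform sequencing error: any base to one of the other three
        if cfg.generic_seq_error > 0:
            err = (rng.random(reads.shape) < cfg.generic_seq_error) & valid
            rows_e, cols_e = np.nonzero(err)
            if rows_e.size:
                cur = reads[rows_e, cols_e]
                base_idx = np.searchsorted(_BASES, cur)
                shift = rng.integers(1, 4, size=rows_e.size)
                reads[rows_e, cols_e] = _BASES[(base_idx + shift) % 4]

        # emit
        for i in range(n_reads):
            rlen = int(lens[i])
            rseq = reads[i, :rlen].tobytes().decode("ascii")
            qname = f"{cfg.read_prefix}_{name}_{i}"
            cig: list[tuple[int, str]] = [(rlen, "M")]
            if cfg.indel_prob > 0 and rng.random() < cfg.indel_prob:
                rseq, cig = _apply_indel(rng, rseq, rlen)
            ref_span = sum(k for k, op in cig if op in "MD")
            if strand == "+":
                pos1 = int(starts[i]) + 1
                sam_seq, sam_cig, flag = rseq, cig, 0
            else:
                # molecule [s, s+span) maps to reference [L-s-span, L-s)
                pos1 = L - int(starts[i]) - ref_span + 1
                sam_seq, sam_cig, flag = revcomp(rseq), cig[::-1], 16
            qual = "I" * len(rseq)
            fastq_parts.append(f"@{qname}\n{rseq}\n+\n{qual}")
            sam_body.append(
                f"{qname}\t{flag}\t{name}\t{pos1}\t60\t{_cigar_str(sam_cig)}"
                f"\t*\t0\t0\t{sam_seq}\t{'I' * len(sam_seq)}"
            )

    expected = truth.copy()
    expected["expected_rate"] = [
        expected_ct_rate(f, eps, e0) for f in expected["fraction"]
    ]
    readthrough = None
    if rt_mode:
        readthrough = pd.DataFrame(
            rt_rows,
            columns=["ref", "pos0", "strand", "fraction", "n_possible", "n_spanning"],
        )
        readthrough["readthrough"] = np.where(
            readthrough["n_possible"] > 0,
            readthrough["n_spanning"] / readthrough["n_possible"].clip(lower=1),
            np.nan,
        )
        readthrough["expected_readthrough"] = 1.0 - readthrough[
            "fraction"
        ] * cfg.rt_stop_prob

    fastq = "\n".join(fastq_parts) + ("\n" if fastq_parts else "")
    sam = "\n".join(header + sam_body) + "\n"
    return SimResult(fastq, sam, truth.copy(), expected, readthrough)


def simulate_rt_stop(
    ref: dict[str, str], truth: pd.DataFrame, cfg: SimConfig
) -> SimResult:
    """Simulate the malononitrile RT-stop chemistry (mode forced)."""
    if cfg.mode != "malononitrile":
        raise ValueError("simulate_rt_stop requires mode='malononitrile'")
    return simulate_library(ref, truth, cfg)


def simulate_site_counts(
    fractions: np.ndarray | list[float],
    coverage: int,
    eps: float,
    e0: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Draw per-site (coverage, n_T) counts from the marginal read model.

    At a site with fraction f each read independently shows T with
    probability ``f*eps + (1 - f*eps)*e0``, so the T count is binomial.
    This is the counts-level marginal of :func:`simulate_library`, used
    when only per-site statistics (not reads) are needed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    f = np.asarray(fractions, dtype=float)
    p = f * eps + (1.0 - f * eps) * e0
    n_T = rng.binomial(coverage, p)
    return pd.DataFrame(
        {
            "fraction": f,
            "coverage": coverage,
            "n_T": n_T,
            "rate": n_T / coverage,
            "expected_rate": p,
        }
    )


def write_fasta(ref: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
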