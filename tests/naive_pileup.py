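"""Independent brute-force per-site recount used as the pileup oracle.

Deliberately shares no code with f5cseq.pileup: SAM text is parsed by
hand and the CIGAR is walked read by read, base by base.
"""

from __future__ import annotations

import re

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def naive_counts(
    sam_text: str,
    ref: dict[str, str],
    min_baseq: int = 20,
    min_mapq: int = 10,
) -> dict[tuple[str, int, str], list[int]]:
    """Per-site [n_T, n_C, n_other] keyed by (ref, pos0, strand)."""
    out: dict[tuple[str, int, str], list[int]] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        qname, flag, rname, pos1, mapq, cigar = (
            f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5],
        )
        seq, qual = f[9], f[10]
        if flag & 0x4 or flag & 0x100 or flag & 0x800:
            continue
        if mapq < min_mapq:
            continue
        strand = "-" if flag & 0x10 else "+"
        want = "G" if strand == "-" else "C"
        hit = {"-": {"A": 0, "G": 1}, "+": {"T": 0, "C": 1}}[strand]
        rseq = ref[rname].upper().replace("U", "T")
        qpos, rpos = 0, pos1 - 1
        for n, op in _CIG_RE.findall(cigar):
            n = int(n)
            if op in "M=X":
                for i in range(n):
                    if rseq[rpos + i] == want:
                        if ord(qual[qpos + i]) - 33 < min_baseq:
                            continue
                        base = seq[qpos + i]
                        if base == "N":
                            continue
                        key = (rname, rpos + i, strand)
                        cnt = out.setdefault(key, [0, 0, 0])
                        cnt[hit.get(base, 2)] += 1
                qpos += n
                rpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
            # H, P consume nothing relevant
    return out
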