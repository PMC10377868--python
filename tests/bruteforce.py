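"""Independent brute-force oracles used to cross-check the encoders.

Every function here recomputes a quantity by direct enumeration — explicit
loops over dipeptides, adjacent positions or sample pairs — sharing no code
path with the package implementations they check.
"""

from __future__ import annotations

import math

from hbpred.descriptors import (
    ALPHABET,
    CODON_DEGENERACY,
    DIPEPTIDES,
    DISTRIBUTION_PERCENTILES,
    N_SENSE_CODONS,
    load_property_partitions,
)


def count_overlapping(seq: str, sub: str) -> int:
    return sum(1 for i in range(len(seq) - len(sub) + 1) if seq[i : i + len(sub)] == sub)


def aac_naive(seq: str) -> list[float]:
    return [seq.count(a) / len(seq) for a in ALPHABET]


def dc_naive(seq: str) -> list[float]:
    return [count_overlapping(seq, d) / (len(seq) - 1) for d in DIPEPTIDES]


def dde_naive(seq: str) -> list[float]:
    out = []
    for d in DIPEPTIDES:
        freq = count_overlapping(seq, d) / (len(seq) - 1)
        tf = (CODON_DEGENERACY[d[0]] / N_SENSE_CODONS) * (
            CODON_DEGENERACY[d[1]] / N_SENSE_CODONS
        )
        tv = tf * (1 - tf) / (len(seq) - 1)
        out.append((freq - tf) / math.sqrt(tv))
    return out


def _groups() -> list[tuple[str, int, set[str]]]:
    table = load_property_partitions()
    return [
        (row["property"], int(row["group"]), set(row["residues"]))
        for _, row in table.iterrows()
    ]


def ctdc_naive(seq: str) -> list[float]:
    return [
        sum(1 for ch in seq if ch in members) / len(seq)
        for _, _, members in _groups()
    ]


def ctdt_naive(seq: str) -> list[float]:
    table = load_property_partitions()
    props = list(dict.fromkeys(table["property"]))
    out = []
    for prop in props:
        sub = table[table["property"] == prop]
        groups = {int(r["group"]): set(r["residues"]) for _, r in sub.iterrows()}
        for a, b in ((1, 2), (1, 3), (2, 3)):
            n = 0
            for i in range(len(seq) - 1):
                x, y = seq[i], seq[i + 1]
                if (x in groups[a] and y in groups[b]) or (
                    x in groups[b] and y in groups[a]
                ):
                    n += 1
            out.append(n / (len(seq) - 1))
    return out


def ctdd_naive(seq: str) -> list[float]:
    out = []
    for _, _, members in _groups():
        total = sum(1 for ch in seq if ch in members)
        for pct in DISTRIBUTION_PERCENTILES:
            if total == 0:
                out.append(0.0)
                continue
            target = max(1, (pct * total) // 100)
            seen = 0
            for pos, ch in enumerate(seq, start=1):
                if ch in members:
                    seen += 1
                    if seen == target:
                        out.append(pos / len(seq) * 100.0)
                        break
    return out


def ctd_naive(seq: str) -> list[float]:
    return ctdc_naive(seq) + ctdt_naive(seq) + ctdd_naive(seq)


def auroc_naive(scores, labels) -> float:
    """Mann-Whitney concordance: P(random positive outscores random negative),
    ties counted one half, by explicit pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def anova_f_naive(values, labels) -> float:
    """One-way ANOVA F by direct sums of squares (two groups)."""
    groups = sorted(set(labels))
    grand = sum(values) / len(values)
    ssb = ssw = 0.0
    dfb = len(groups) - 1
    dfw = len(values) - len(groups)
    for g in groups:
        vals = [v for v, l in zip(values, labels) if l == g]
        mean = sum(vals) / len(vals)
        ssb += len(vals) * (mean - grand) ** 2
        ssw += sum((v - mean) ** 2 for v in vals)
    return (ssb / dfb) / (ssw / dfw)
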