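"""Brute-force enumeration oracles for the descriptor encoders.

Every oracle recomputes a descriptor with explicit Python loops over
all index tuples, straight from the defining formulas, sharing nothing
with the package implementation except the published constant tables
(alphabet, group partitions, physicochemical scales).
"""

import math

from acpkit.encoders import (
    ALPHABET,
    CT_CLASSES,
    CTD_PROPERTIES,
    GAAC_GROUPS,
    _HYDROPHOBICITY,
    _HYDROPHILICITY,
    _SIDECHAIN_MASS,
)

GROUP_NAMES = list(GAAC_GROUPS)


def aac_oracle(seq):
    return [sum(1 for c in seq if c == a) / len(seq) for a in ALPHABET]


def kmer_oracle(seq, k):
    out = []
    denom = len(seq) - k + 1
    for combo in _tuples(ALPHABET, k):
        count = 0
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] == combo[j] for j in range(k)):
                count += 1
        out.append(count / denom)
    return out


def cksaap_oracle(seq, kmax):
    out = []
    for k in range(kmax + 1):
        denom = len(seq) - k - 1
        for a in ALPHABET:
            for b in ALPHABET:
                count = 0
                for i in range(len(seq) - k - 1):
                    if seq[i] == a and seq[i + k + 1] == b:
                        count += 1
                out.append(count / denom)
    return out


def _group_of(residue):
    for name, members in GAAC_GROUPS.items():
        if residue in members:
            return name
    raise AssertionError(residue)


def grouped_kmer_oracle(seq, k):
    groups = [_group_of(c) for c in seq]
    denom = len(seq) - k + 1
    out = []
    for combo in _tuples(GROUP_NAMES, k):
        count = 0
        for i in range(len(seq) - k + 1):
            if all(groups[i + j] == combo[j] for j in range(k)):
                count += 1
        out.append(count / denom)
    return out


def cksaagp_oracle(seq, kmax):
    groups = [_group_of(c) for c in seq]
    out = []
    for k in range(kmax + 1):
        denom = len(seq) - k - 1
        for g1 in GROUP_NAMES:
            for g2 in GROUP_NAMES:
                count = 0
                for i in range(len(seq) - k - 1):
                    if groups[i] == g1 and groups[i + k + 1] == g2:
                        count += 1
                out.append(count / denom)
    return out


def _ct_class(residue):
    for c, members in enumerate(CT_CLASSES, start=1):
        if residue in members:
            return c
    raise AssertionError(residue)


def ct_oracle(seq):
    classes = [_ct_class(c) for c in seq]
    out = []
    for c1 in range(1, 8):
        for c2 in range(1, 8):
            for c3 in range(1, 8):
                count = 0
                for i in range(len(seq) - 2):
                    if classes[i:i + 3] == [c1, c2, c3]:
                        count += 1
                out.append(count / (len(seq) - 2))
    return out


def ctd_oracle(seq, which):
    n = len(seq)
    out = []
    for prop, groups in CTD_PROPERTIES.items():
        labels = []
        for c in seq:
            for g, members in enumerate(groups, start=1):
                if c in members:
                    labels.append(g)
                    break
        if which == "C":
            for g in (1, 2, 3):
                out.append(sum(1 for lab in labels if lab == g) / n)
        elif which == "T":
            for r, s in ((1, 2), (1, 3), (2, 3)):
                count = 0
                for i in range(n - 1):
                    pair = (labels[i], labels[i + 1])
                    if pair == (r, s) or pair == (s, r):
                        count += 1
                out.append(count / (n - 1))
        else:
            for g in (1, 2, 3):
                positions = [i + 1 for i in range(n) if labels[i] == g]
                if not positions:
                    out.extend([0.0] * 5)
                    continue
                for pt in (0, 25, 50, 75, 100):
                    if pt == 0:
                        pos = positions[0]
                    else:
                        pos = positions[math.ceil(pt / 100 * len(positions)) - 1]
                    out.append(pos / n * 100.0)
    return out


def _standardized(scale):
    vals = [scale[a] for a in ALPHABET]
    mean = sum(vals) / 20
    var = sum((v - mean) ** 2 for v in vals) / 20
    sd = math.sqrt(var)
    return {a: (scale[a] - mean) / sd for a in ALPHABET}


def paac_oracle(seq, lam, w):
    n = len(seq)
    scales = [_standardized(s)
              for s in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS)]
    thetas = []
    for j in range(1, lam + 1):
        terms = []
        for i in range(n - j):
            corr = sum(
                (s[seq[i + j]] - s[seq[i]]) ** 2 for s in scales
            ) / 3
            terms.append(corr)
        thetas.append(sum(terms) / len(terms))
    freq = [sum(1 for c in seq if c == a) / n for a in ALPHABET]
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freq] + [w * t / denom for t in thetas]


def apaac_oracle(seq, lam, w):
    n = len(seq)
    h1 = _standardized(_HYDROPHOBICITY)
    h2 = _standardized(_HYDROPHILICITY)
    taus = []
    for j in range(1, lam + 1):
        for scale in (h1, h2):
            terms = [scale[seq[i]] * scale[seq[i + j]] for i in range(n - j)]
            taus.append(sum(terms) / len(terms))
    freq = [sum(1 for c in seq if c == a) / n for a in ALPHABET]
    denom = 1.0 + w * sum(taus)
    return [f / denom for f in freq] + [w * t / denom for t in taus]


def _tuples(symbols, k):
    if k == 1:
        return [(s,) for s in symbols]
    return [t + (s,) for t in _tuples(symbols, k - 1) for s in symbols]
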