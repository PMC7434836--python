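"""Twelve peptide sequence descriptor families with a resolvable naming grammar.

The encoders turn a peptide sequence over the 20 standard amino acids
into a fixed-length numeric vector.  Five strategy families are covered:

=========  =====================================================  =========
family     encoders                                               dimension
=========  =====================================================  =========
k-mer      AAC, DPC, TPC, CKSAAP                                  20 / 400 / 8000 / 400·(kmax+1)
grouped    GAAC, GDPC, GTPC, CKSAAGP (5 physicochemical groups)   5 / 25 / 125 / 25·(kmax+1)
triad      CT (conjoint triad, 7 residue classes)                 343
CTD        CTDC, CTDT, CTDD over 13 physicochemical properties    39 / 39 / 195
pseudo     PAAC, APAAC (sequence-order correlation terms)         20+λ / 20+2λ
=========  =====================================================  =========

Every feature carries a structured name ("GL.gap4", "Pc2.Hydrophobicity.8",
"polarizability.2.residue0", ...) that renders to and parses from a
canonical text form, so a low-dimensional model is just a manifest of
names and :func:`encode_selected` can recompute exactly those columns
for new peptides.

All composition-family vectors (AAC, DPC, TPC, GAAC, GDPC, GTPC and each
gap block of CKSAAP / CKSAAGP) sum to 1 for any valid input.  PAAC and
APAAC reduce exactly to AAC in the λ→0 and w→0 limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, AcpkitError, LabeledDataset, Peptide

# --------------------------------------------------------------------------
# Property tables
# --------------------------------------------------------------------------

#: 5-way physicochemical grouping of the 20 residues (GAAC family).
GAAC_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positivecharge": "KRH",
    "negativecharge": "DE",
    "uncharged": "STCPNQ",
}
GAAC_GROUP_NAMES = tuple(GAAC_GROUPS)

#: Conjoint-triad 7-class residue partition (dipole / side-chain volume).
CT_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: 13-property CTD set; each property partitions the 20 residues into
#: three groups (group 1, 2, 3).
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# residue order A R N D C Q E G H I L K M F P S T W Y V (classical tables)
_PAAC_ORDER = "ARNDCQEGHILKMFPSTWYV"
_HYDROPHOBICITY = dict(zip(_PAAC_ORDER, (
    0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38,
    1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08,
)))
_HYDROPHILICITY = dict(zip(_PAAC_ORDER, (
    -0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
    -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5,
)))
_SIDECHAIN_MASS = dict(zip(_PAAC_ORDER, (
    15.0, 101.0, 58.0, 59.0, 47.0, 72.0, 73.0, 1.0, 82.0, 57.0,
    57.0, 73.0, 75.0, 91.0, 42.0, 31.0, 45.0, 130.0, 107.0, 43.0,
)))

ENCODER_IDS = (
    "AAC", "DPC", "TPC", "CKSAAP", "GAAC", "GDPC", "GTPC", "CKSAAGP",
    "CT", "CTDC", "CTDT", "CTDD", "PAAC", "APAAC",
)

#: Toolkit defaults for parameterised encoders.
DEFAULT_CKSAAP_KMAX = 5
DEFAULT_CKSAAGP_KMAX = 5
DEFAULT_PAAC_LAMBDA = 8
DEFAULT_PAAC_WEIGHT = 0.05

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
_GROUP_OF = {a: g for g, members in GAAC_GROUPS.items() for a in members}
_GROUP_INDEX = {g: i for i, g in enumerate(GAAC_GROUP_NAMES)}
_CT_CLASS_OF = {a: c + 1 for c, members in enumerate(CT_CLASSES) for a in members}

# sanity: every partition covers the 20 residues exactly once
for _name, _groups in {"GAAC": tuple(GAAC_GROUPS.values()),
                       "CT": CT_CLASSES,
                       **CTD_PROPERTIES}.items():
    assert sorted("".join(_groups)) == sorted(ALPHABET), _name


class EncoderLengthError(AcpkitError):
    """Sequence shorter than the encoder's minimum length."""


class FeatureNameError(AcpkitError):
    """A feature name does not conform to the naming grammar."""


# --------------------------------------------------------------------------
# Feature names
# --------------------------------------------------------------------------

_CTDT_PAIR_LABEL = {(1, 2): "Tr1221", (1, 3): "Tr1331", (2, 3): "Tr2332"}
_CTDT_LABEL_PAIR = {v: k for k, v in _CTDT_PAIR_LABEL.items()}
_CTDD_POINTS = (0, 25, 50, 75, 100)


@dataclass(frozen=True)
class FeatureName:
    """A structured feature name: encoder id plus encoder-specific components.

    ``render`` and ``parse`` are mutual inverses on the canonical text
    form, e.g. ``FeatureName("CKSAAP", ("G", "L", 4))`` ↔ ``"GL.gap4"``.
    Parsing is case-sensitive.
    """

    encoder: str
    components: tuple

    def render(self) -> str:
        e, c = self.encoder, self.components
        if e in ("AAC", "DPC", "TPC"):
            return "".join(c)
        if e == "CKSAAP":
            return f"{c[0]}{c[1]}.gap{c[2]}"
        if e in ("GAAC", "GDPC", "GTPC"):
            return ".".join(c)
        if e == "CKSAAGP":
            return f"{c[0]}.{c[1]}.gap{c[2]}"
        if e == "CT":
            return "ct" + "".join(str(x) for x in c)
        if e == "CTDC":
            return f"{c[0]}.G{c[1]}"
        if e == "CTDT":
            return f"{c[0]}.{_CTDT_PAIR_LABEL[c[1]]}"
        if e == "CTDD":
            return f"{c[0]}.{c[1]}.residue{c[2]}"
        if e == "PAAC":
            return f"Xc1.{c[1]}" if c[0] == "Xc1" else f"Xc2.lambda{c[1]}"
        if e == "APAAC":
            return f"Pc1.{c[1]}" if c[0] == "Pc1" else f"Pc2.{c[1]}.{c[2]}"
        raise FeatureNameError(f"unknown encoder {e!r}")

    def __str__(self) -> str:
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "FeatureName":
        """Parse a canonical feature name; inverse of :meth:`render`."""
        parts = text.split(".")
        try:
            return cls._parse_parts(text, parts)
        except FeatureNameError:
            raise
        except (KeyError, ValueError, IndexError) as exc:
            raise FeatureNameError(_parse_error(text)) from exc

    @classmethod
    def _parse_parts(cls, text: str, parts: list[str]) -> "FeatureName":
        if len(parts) == 1:
            token = parts[0]
            if 1 <= len(token) <= 3 and all(a in _AA_INDEX for a in token):
                return cls(("AAC", "DPC", "TPC")[len(token) - 1], tuple(token))
            if token in GAAC_GROUPS:
                return cls("GAAC", (token,))
            if token.startswith("ct") and len(token) == 5:
                classes = tuple(int(x) for x in token[2:])
                if all(1 <= x <= 7 for x in classes):
                    return cls("CT", classes)
            raise FeatureNameError(_parse_error(text))
        if parts[0] in ("Xc1", "Xc2"):
            if len(parts) != 2:
                raise FeatureNameError(_parse_error(text))
            if parts[0] == "Xc1" and parts[1] in _AA_INDEX:
                return cls("PAAC", ("Xc1", parts[1]))
            if parts[0] == "Xc2" and parts[1].startswith("lambda"):
                return cls("PAAC", ("Xc2", _positive_int(parts[1][6:])))
            raise FeatureNameError(_parse_error(text))
        if parts[0] in ("Pc1", "Pc2"):
            if parts[0] == "Pc1" and len(parts) == 2 and parts[1] in _AA_INDEX:
                return cls("APAAC", ("Pc1", parts[1]))
            if (parts[0] == "Pc2" and len(parts) == 3
                    and parts[1] in ("Hydrophobicity", "Hydrophilicity")):
                return cls("APAAC", ("Pc2", parts[1], _positive_int(parts[2])))
            raise FeatureNameError(_parse_error(text))
        if parts[0] in CTD_PROPERTIES:
            if len(parts) == 2 and parts[1] in ("G1", "G2", "G3"):
                return cls("CTDC", (parts[0], int(parts[1][1])))
            if len(parts) == 2 and parts[1] in _CTDT_LABEL_PAIR:
                return cls("CTDT", (parts[0], _CTDT_LABEL_PAIR[parts[1]]))
            if (len(parts) == 3 and parts[1] in ("1", "2", "3")
                    and parts[2].startswith("residue")):
                point = int(parts[2][7:])
                if point in _CTDD_POINTS:
                    return cls("CTDD", (parts[0], int(parts[1]), point))
            raise FeatureNameError(_parse_error(text))
        if parts[-1].startswith("gap"):
            gap = _nonneg_int(parts[-1][3:])
            head = parts[:-1]
            if (len(head) == 1 and len(head[0]) == 2
                    and all(a in _AA_INDEX for a in head[0])):
                return cls("CKSAAP", (head[0][0], head[0][1], gap))
            if len(head) == 2 and all(g in GAAC_GROUPS for g in head):
                return cls("CKSAAGP", (head[0], head[1], gap))
            raise FeatureNameError(_parse_error(text))
        if all(g in GAAC_GROUPS for g in parts):
            if len(parts) == 2:
                return cls("GDPC", tuple(parts))
            if len(parts) == 3:
                return cls("GTPC", tuple(parts))
        raise FeatureNameError(_parse_error(text))


def _positive_int(text: str) -> int:
    value = int(text)
    if value < 1:
        raise ValueError(text)
    return value


def _nonneg_int(text: str) -> int:
    value = int(text)
    if value < 0:
        raise ValueError(text)
    return value


def _parse_error(text: str) -> str:
    return (
        f"cannot resolve feature name {text!r}; expected one of: residue "
        "k-mer ('K', 'GL', 'GLK'), 'AB.gapK', group names "
        "('aliphatic', 'aliphatic.aromatic', ... , 'g1.g2.gapK'), 'ctXYZ', "
        "'<property>.G1|Tr1221|1.residue0', 'Xc1.A'/'Xc2.lambdaJ', "
        "'Pc1.A'/'Pc2.Hydrophobicity.J'"
    )


# --------------------------------------------------------------------------
# Name vectors (column orders are deterministic for fixed parameters)
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _kmer_names(k: int) -> tuple[str, ...]:
    scheme = ("AAC", "DPC", "TPC")[k - 1]
    return tuple(
        FeatureName(scheme, combo).render()
        for combo in product(ALPHABET, repeat=k)
    )


@lru_cache(maxsize=None)
def _cksaap_names(kmax: int) -> tuple[str, ...]:
    return tuple(
        FeatureName("CKSAAP", (a, b, k)).render()
        for k in range(kmax + 1)
        for a, b in product(ALPHABET, repeat=2)
    )


@lru_cache(maxsize=None)
def _grouped_kmer_names(k: int) -> tuple[str, ...]:
    scheme = ("GAAC", "GDPC", "GTPC")[k - 1]
    return tuple(
        FeatureName(scheme, combo).render()
        for combo in product(GAAC_GROUP_NAMES, repeat=k)
    )


@lru_cache(maxsize=None)
def _cksaagp_names(kmax: int) -> tuple[str, ...]:
    return tuple(
        FeatureName("CKSAAGP", (g1, g2, k)).render()
        for k in range(kmax + 1)
        for g1, g2 in product(GAAC_GROUP_NAMES, repeat=2)
    )


@lru_cache(maxsize=None)
def _ct_names() -> tuple[str, ...]:
    return tuple(
        FeatureName("CT", combo).render()
        for combo in product(range(1, 8), repeat=3)
    )


@lru_cache(maxsize=None)
def _ctd_names(which: str) -> tuple[str, ...]:
    names: list[str] = []
    for prop in CTD_PROPERTIES:
        if which == "C":
            names += [FeatureName("CTDC", (prop, g)).render() for g in (1, 2, 3)]
        elif which == "T":
            names += [FeatureName("CTDT", (prop, pair)).render()
                      for pair in ((1, 2), (1, 3), (2, 3))]
        else:
            names += [FeatureName("CTDD", (prop, g, pt)).render()
                      for g in (1, 2, 3) for pt in _CTDD_POINTS]
    return tuple(names)


@lru_cache(maxsize=None)
def _paac_names(scheme: str, lam: int) -> tuple[str, ...]:
    if scheme == "PAAC":
        names = [FeatureName("PAAC", ("Xc1", a)).render() for a in ALPHABET]
        names += [FeatureName("PAAC", ("Xc2", j)).render()
                  for j in range(1, lam + 1)]
    else:
        names = [FeatureName("APAAC", ("Pc1", a)).render() for a in ALPHABET]
        for j in range(1, lam + 1):
            names.append(FeatureName("APAAC", ("Pc2", "Hydrophobicity", j)).render())
            names.append(FeatureName("APAAC", ("Pc2", "Hydrophilicity", j)).render())
    return tuple(names)


# --------------------------------------------------------------------------
# Single-sequence encoders
# --------------------------------------------------------------------------

def _require_length(seq: str, minimum: int, scheme: str) -> None:
    if len(seq) < minimum:
        raise EncoderLengthError(
            f"{scheme} requires length >= {minimum}, got {len(seq)}"
        )


def encode_kmer_family(peptide: Peptide | str, scheme: str) -> np.ndarray:
    """AAC / DPC / TPC: frequencies of residue k-mers (k = 1, 2, 3).

    The vector entry for k-mer ``w`` is (occurrences of ``w``) / (N−k+1),
    i.e. count over denominator N, N−1 or N−2.  Dimensions 20 / 400 / 8000,
    names in lexicographic order.
    """
    seq = _seq_of(peptide)
    k = {"AAC": 1, "DPC": 2, "TPC": 3}[scheme]
    _require_length(seq, k, scheme)
    idx = np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    code = idx[: len(seq) - k + 1].copy()
    for j in range(1, k):
        code = code * 20 + idx[j: len(seq) - k + 1 + j]
    vec = np.bincount(code, minlength=20 ** k).astype(float)
    return vec / (len(seq) - k + 1)


def encode_cksaap(peptide: Peptide | str, kmax: int = DEFAULT_CKSAAP_KMAX) -> np.ndarray:
    """Composition of k-spaced residue pairs for every gap k = 0..kmax.

    For gap ``k`` the feature for ordered pair (a, b) counts positions
    ``i`` with ``seq[i] == a`` and ``seq[i+k+1] == b``, divided by
    N−k−1 possible positions.  400 features per gap block, each block
    summing to 1; names ``"AB.gapk"``.
    """
    seq = _seq_of(peptide)
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    _require_length(seq, kmax + 2, f"CKSAAP(kmax={kmax})")
    idx = np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    blocks = []
    for k in range(kmax + 1):
        npos = len(seq) - k - 1
        code = idx[:npos] * 20 + idx[k + 1:]
        blocks.append(np.bincount(code, minlength=400).astype(float) / npos)
    return np.concatenate(blocks)


def encode_grouped_family(
    peptide: Peptide | str, scheme: str, kmax: int = DEFAULT_CKSAAGP_KMAX
) -> np.ndarray:
    """GAAC / GDPC / GTPC / CKSAAGP: k-mer compositions over the 5-group alphabet.

    Residues are first collapsed to their physicochemical group
    (aliphatic, aromatic, positive charge, negative charge, uncharged);
    the corresponding k-mer computation then runs over the 5-letter
    alphabet.  Dimensions 5 / 25 / 125 / 25·(kmax+1).
    """
    seq = _seq_of(peptide)
    gidx = np.array([_GROUP_INDEX[_GROUP_OF[a]] for a in seq], dtype=np.int64)
    if scheme in ("GAAC", "GDPC", "GTPC"):
        k = {"GAAC": 1, "GDPC": 2, "GTPC": 3}[scheme]
        _require_length(seq, k, scheme)
        code = gidx[: len(seq) - k + 1].copy()
        for j in range(1, k):
            code = code * 5 + gidx[j: len(seq) - k + 1 + j]
        vec = np.bincount(code, minlength=5 ** k).astype(float)
        return vec / (len(seq) - k + 1)
    if scheme != "CKSAAGP":
        raise ValueError(f"unknown grouped scheme {scheme!r}")
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    _require_length(seq, kmax + 2, f"CKSAAGP(kmax={kmax})")
    blocks = []
    for k in range(kmax + 1):
        npos = len(seq) - k - 1
        code = gidx[:npos] * 5 + gidx[k + 1:]
        blocks.append(np.bincount(code, minlength=25).astype(float) / npos)
    return np.concatenate(blocks)


def encode_ct(peptide: Peptide | str, normalization: str = "frequency") -> np.ndarray:
    """Conjoint triad: frequencies of overlapping triads over 7 residue classes.

    Residues collapse to 7 classes; triads equivalent classwise (e.g.
    GLM and VFT) map to the same feature.  343 features.  With the
    default ``"frequency"`` normalisation each feature is
    count / (N−2); ``"minmax"`` applies the (count − min) / max variant
    over the 343 raw counts instead.
    """
    seq = _seq_of(peptide)
    _require_length(seq, 3, "CT")
    cidx = np.array([_CT_CLASS_OF[a] - 1 for a in seq], dtype=np.int64)
    code = cidx[:-2] * 49 + cidx[1:-1] * 7 + cidx[2:]
    counts = np.bincount(code, minlength=343).astype(float)
    if normalization == "frequency":
        return counts / (len(seq) - 2)
    if normalization == "minmax":
        top = counts.max()
        return (counts - counts.min()) / top if top > 0 else counts
    raise ValueError(f"unknown CT normalization {normalization!r}")


def encode_ctd(peptide: Peptide | str, which: str) -> np.ndarray:
    """Composition / Transition / Distribution descriptors.

    For each of the 13 physicochemical properties, residues fall into
    three groups and:

    - ``which="C"``: the fraction of residues in each group (3 values,
      summing to 1);
    - ``which="T"``: Tr(r, s) = (adjacent pairs rs or sr) / (N−1) for
      the unordered group pairs (1,2), (1,3), (2,3);
    - ``which="D"``: for each group, the 1-based sequence positions of
      its first, 25%, 50%, 75% and 100% occurrences, each divided by N
      and scaled ×100.  A group with no occurrences contributes five
      zeros.
    """
    seq = _seq_of(peptide)
    if which not in ("C", "T", "D"):
        raise ValueError(f"which must be 'C', 'T' or 'D', got {which!r}")
    n = len(seq)
    if which == "T":
        _require_length(seq, 2, "CTDT")
    out: list[float] = []
    for prop, groups in CTD_PROPERTIES.items():
        gmap = {a: g + 1 for g, members in enumerate(groups) for a in members}
        labels = [gmap[a] for a in seq]
        if which == "C":
            for g in (1, 2, 3):
                out.append(labels.count(g) / n)
        elif which == "T":
            for r, s in ((1, 2), (1, 3), (2, 3)):
                count = sum(
                    1 for i in range(n - 1)
                    if {labels[i], labels[i + 1]} == {r, s}
                )
                out.append(count / (n - 1))
        else:
            for g in (1, 2, 3):
                positions = [i + 1 for i, lab in enumerate(labels) if lab == g]
                if not positions:
                    out.extend([0.0] * 5)
                    continue
                total = len(positions)
                for pt in _CTDD_POINTS:
                    rank = 1 if pt == 0 else math.ceil(pt / 100 * total)
                    out.append(positions[rank - 1] / n * 100.0)
    return np.array(out)


def _standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    values = np.array([scale[a] for a in ALPHABET])
    return dict(zip(ALPHABET, (values - values.mean()) / values.std()))


@lru_cache(maxsize=None)
def _paac_scales() -> tuple[dict[str, float], ...]:
    return tuple(
        _standardize_scale(s)
        for s in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS)
    )


def encode_paac_family(
    peptide: Peptide | str,
    scheme: str,
    lam: int = DEFAULT_PAAC_LAMBDA,
    w: float = DEFAULT_PAAC_WEIGHT,
) -> np.ndarray:
    """Pseudo / amphiphilic pseudo amino-acid composition.

    Augments the composition with λ sequence-order correlation terms
    built from physicochemical scales standardised to zero mean and
    unit variance over the 20 residues.

    PAAC (dimension 20+λ): θ_j averages, over all positions i, the mean
    squared scale difference between residues i and i+j across the
    hydrophobicity, hydrophilicity and side-chain-mass scales;
    Xc1.a = f_a / (1 + w·Σθ), Xc2.j = w·θ_j / (1 + w·Σθ), with f the
    normalised residue frequencies.

    APAAC (dimension 20+2λ): the order terms keep hydrophobicity and
    hydrophilicity separate, using products H(i)·H(i+j) instead of
    squared differences; Pc1.a and Pc2.<Property>.j are normalised the
    same way.

    λ=0, or w=0 for the composition block, reduces exactly to AAC.
    """
    seq = _seq_of(peptide)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if scheme not in ("PAAC", "APAAC"):
        raise ValueError(f"unknown pseudo-composition scheme {scheme!r}")
    _require_length(seq, lam + 1, f"{scheme}(lambda={lam})")
    n = len(seq)
    freq = encode_kmer_family(seq, "AAC")
    h1, h2, mass = _paac_scales()
    if scheme == "PAAC":
        theta = np.empty(lam)
        for j in range(1, lam + 1):
            corr = [
                np.mean([
                    (s[seq[i + j]] - s[seq[i]]) ** 2 for s in (h1, h2, mass)
                ])
                for i in range(n - j)
            ]
            theta[j - 1] = float(np.mean(corr))
        denom = 1.0 + w * theta.sum()
        return np.concatenate([freq / denom, w * theta / denom])
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        for k, scale in enumerate((h1, h2)):
            vals = [scale[seq[i]] * scale[seq[i + j]] for i in range(n - j)]
            tau[2 * (j - 1) + k] = float(np.mean(vals))
    denom = 1.0 + w * tau.sum()
    return np.concatenate([freq / denom, w * tau / denom])


def _seq_of(peptide: Peptide | str) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else peptide


# --------------------------------------------------------------------------
# Dataset-level encoding
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """An n-peptides × d-features table with encoder provenance per column.

    ``data`` is a :class:`pandas.DataFrame` (index = peptide ids,
    columns = rendered feature names); ``tags`` maps each name to its
    ``(encoder id, parameter dict)``.
    """

    data: pd.DataFrame
    tags: dict[str, tuple[str, dict]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise FeatureNameError(f"features not in matrix: {missing[:5]}")
        return FeatureMatrix(
            self.data[list(names)].copy(),
            {n: self.tags[n] for n in names if n in self.tags},
        )

    @staticmethod
    def hstack(matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("no matrices to stack")
        data = pd.concat([m.data for m in matrices], axis=1)
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise FeatureNameError(f"duplicate feature names: {dupes[:5]}")
        tags: dict[str, tuple[str, dict]] = {}
        for m in matrices:
            tags.update(m.tags)
        return FeatureMatrix(data, tags)

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="id")

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "FeatureMatrix":
        data = pd.read_csv(path, sep=sep, index_col="id")
        data.index = data.index.astype(str)
        tags = {}
        for name in data.columns:
            try:
                parsed = FeatureName.parse(str(name))
                tags[str(name)] = (parsed.encoder, {})
            except FeatureNameError:
                tags[str(name)] = ("unknown", {})
        return cls(data, tags)


def _encoder_spec(encoder: str, params: dict) -> tuple[
    tuple[str, ...], Callable[[str], np.ndarray], dict
]:
    """Resolve an encoder id + params to (names, per-sequence fn, params)."""
    if encoder in ("AAC", "DPC", "TPC"):
        k = {"AAC": 1, "DPC": 2, "TPC": 3}[encoder]
        return _kmer_names(k), lambda s: encode_kmer_family(s, encoder), {}
    if encoder == "CKSAAP":
        kmax = params.get("kmax", DEFAULT_CKSAAP_KMAX)
        return (_cksaap_names(kmax),
                lambda s: encode_cksaap(s, kmax), {"kmax": kmax})
    if encoder in ("GAAC", "GDPC", "GTPC"):
        k = {"GAAC": 1, "GDPC": 2, "GTPC": 3}[encoder]
        return (_grouped_kmer_names(k),
                lambda s: encode_grouped_family(s, encoder), {})
    if encoder == "CKSAAGP":
        kmax = params.get("kmax", DEFAULT_CKSAAGP_KMAX)
        return (_cksaagp_names(kmax),
                lambda s: encode_grouped_family(s, "CKSAAGP", kmax),
                {"kmax": kmax})
    if encoder == "CT":
        norm = params.get("normalization", "frequency")
        return (_ct_names(),
                lambda s: encode_ct(s, norm), {"normalization": norm})
    if encoder in ("CTDC", "CTDT", "CTDD"):
        which = encoder[-1]
        return _ctd_names(which), lambda s: encode_ctd(s, which), {}
    if encoder in ("PAAC", "APAAC"):
        lam = params.get("lambda", DEFAULT_PAAC_LAMBDA)
        w = params.get("w", DEFAULT_PAAC_WEIGHT)
        return (_paac_names(encoder, lam),
                lambda s: encode_paac_family(s, encoder, lam, w),
                {"lambda": lam, "w": w})
    raise ValueError(f"unknown encoder {encoder!r}; known: {ENCODER_IDS}")


def encode_dataset(
    peptides: Sequence[Peptide] | LabeledDataset,
    encoder: str,
    skip_short: bool = False,
    **params,
) -> FeatureMatrix:
    """Encode every peptide with one encoder into a :class:`FeatureMatrix`.

    A sequence failing the encoder's length precondition raises (with
    the peptide id attached) unless ``skip_short`` drops the record with
    a warning.
    """
    import warnings as _warnings

    if isinstance(peptides, LabeledDataset):
        peptides = peptides.peptides
    names, fn, resolved = _encoder_spec(encoder, params)
    rows, ids = [], []
    for pep in peptides:
        try:
            rows.append(fn(pep.sequence))
        except EncoderLengthError as exc:
            if skip_short:
                _warnings.warn(f"skipping {pep.id!r}: {exc}")
                continue
            raise EncoderLengthError(f"peptide {pep.id!r}: {exc}") from exc
        ids.append(pep.id)
    data = pd.DataFrame(
        np.array(rows).reshape(len(ids), len(names)),
        index=ids, columns=list(names),
    )
    tags = {n: (encoder, dict(resolved)) for n in names}
    return FeatureMatrix(data, tags)


def encode_many(
    peptides: Sequence[Peptide] | LabeledDataset,
    encoders: Sequence[str | tuple[str, dict]],
    skip_short: bool = False,
) -> FeatureMatrix:
    """Encode with several encoders and stack the columns.

    With ``skip_short``, a record failing *any* requested encoder's
    length minimum is dropped from the stacked result (rows must align
    across encoders).
    """
    matrices = []
    for spec in encoders:
        encoder, params = spec if isinstance(spec, tuple) else (spec, {})
        matrices.append(
            encode_dataset(peptides, encoder, skip_short=skip_short, **params)
        )
    if skip_short:
        kept = set(matrices[0].ids)
        for m in matrices[1:]:
            kept &= set(m.ids)
        order = [i for i in matrices[0].ids if i in kept]
        matrices = [
            FeatureMatrix(m.data.loc[order], m.tags) for m in matrices
        ]
    return FeatureMatrix.hstack(matrices)


# --------------------------------------------------------------------------
# Feature resolution and selected-column encoding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureResolution:
    """Where a named feature lives: encoder, parameters, column index."""

    name: str
    encoder: str
    params: tuple  # hashable (key, value) pairs
    index: int

    @property
    def params_dict(self) -> dict:
        return dict(self.params)

    def compute(self, peptide: Peptide | str) -> float:
        """Compute this single feature for one peptide."""
        _, fn, _ = _encoder_spec(self.encoder, self.params_dict)
        return float(fn(_seq_of(peptide))[self.index])


def resolve_feature(
    name: str,
    cksaap_kmax: int = DEFAULT_CKSAAP_KMAX,
    cksaagp_kmax: int = DEFAULT_CKSAAGP_KMAX,
    paac_lambda: int = DEFAULT_PAAC_LAMBDA,
    paac_w: float = DEFAULT_PAAC_WEIGHT,
) -> FeatureResolution:
    """Map a feature name to (encoder, parameters, column index).

    Gap-pair features resolve with the minimal ``kmax`` (their value
    does not depend on it, and the length precondition is weakest).
    Pseudo-composition features resolve against the toolkit λ and w
    defaults, widening λ when an order term demands it; their values
    depend on λ and w through the shared denominator, so resolutions
    record the parameters they assumed.
    """
    parsed = FeatureName.parse(name)
    e, c = parsed.encoder, parsed.components
    params: dict = {}
    if e in ("AAC", "DPC", "TPC"):
        k = len(c)
        index = 0
        for a in c:
            index = index * 20 + _AA_INDEX[a]
    elif e == "CKSAAP":
        # gap blocks are independent of kmax, so resolve minimally: the
        # same value at the weakest length precondition (N >= gap+2)
        params = {"kmax": c[2]}
        index = c[2] * 400 + _AA_INDEX[c[0]] * 20 + _AA_INDEX[c[1]]
    elif e in ("GAAC", "GDPC", "GTPC"):
        index = 0
        for g in c:
            index = index * 5 + _GROUP_INDEX[g]
    elif e == "CKSAAGP":
        params = {"kmax": c[2]}
        index = c[2] * 25 + _GROUP_INDEX[c[0]] * 5 + _GROUP_INDEX[c[1]]
    elif e == "CT":
        index = (c[0] - 1) * 49 + (c[1] - 1) * 7 + (c[2] - 1)
    elif e == "CTDC":
        index = list(CTD_PROPERTIES).index(c[0]) * 3 + (c[1] - 1)
    elif e == "CTDT":
        pairs = ((1, 2), (1, 3), (2, 3))
        index = list(CTD_PROPERTIES).index(c[0]) * 3 + pairs.index(c[1])
    elif e == "CTDD":
        index = (list(CTD_PROPERTIES).index(c[0]) * 15
                 + (c[1] - 1) * 5 + _CTDD_POINTS.index(c[2]))
    elif e == "PAAC":
        lam = max(paac_lambda, c[1]) if c[0] == "Xc2" else paac_lambda
        params = {"lambda": lam, "w": paac_w}
        index = _AA_INDEX[c[1]] if c[0] == "Xc1" else 20 + c[1] - 1
    elif e == "APAAC":
        lam = max(paac_lambda, c[2]) if c[0] == "Pc2" else paac_lambda
        params = {"lambda": lam, "w": paac_w}
        if c[0] == "Pc1":
            index = _AA_INDEX[c[1]]
        else:
            offset = 0 if c[1] == "Hydrophobicity" else 1
            index = 20 + 2 * (c[2] - 1) + offset
    else:  # pragma: no cover - parse() limits encoders
        raise FeatureNameError(name)
    return FeatureResolution(
        name=name, encoder=e, params=tuple(sorted(params.items())), index=index
    )


def encode_selected(
    peptides: Sequence[Peptide] | LabeledDataset,
    names: Sequence[str],
    **resolve_params,
) -> FeatureMatrix:
    """Compute exactly the named features (column order = input order).

    Names are grouped by (encoder, parameters) so each underlying
    encoder runs once per peptide; columns equal the corresponding
    columns of the full encoder output.
    """
    if isinstance(peptides, LabeledDataset):
        peptides = peptides.peptides
    resolutions = [resolve_feature(str(n), **resolve_params) for n in names]
    ids = [p.id for p in peptides]
    out = pd.DataFrame(index=ids, dtype=float)
    by_encoder: dict[tuple, list[FeatureResolution]] = {}
    for res in resolutions:
        by_encoder.setdefault((res.encoder, res.params), []).append(res)
    columns: dict[str, np.ndarray] = {}
    for (encoder, params), group in by_encoder.items():
        pdict = dict(params)
        _, fn, _ = _encoder_spec(encoder, pdict)
        rows = []
        for pep in peptides:
            try:
                rows.append(fn(pep.sequence))
            except EncoderLengthError as exc:
                raise EncoderLengthError(f"peptide {pep.id!r}: {exc}") from exc
        full = np.array(rows).reshape(len(ids), -1)
        for res in group:
            columns[res.name] = full[:, res.index]
    data = pd.DataFrame(
        {res.name: columns[res.name] for res in resolutions},
        index=ids,
    ) if resolutions else pd.DataFrame(index=ids)
    tags = {res.name: (res.encoder, res.params_dict) for res in resolutions}
    return FeatureMatrix(data, tags)


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[str]:
    """Read a feature manifest: one name per line, ``#`` comments allowed."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            FeatureName.parse(line)  # fail fast on bad names
            names.append(line)
    return names


def write_manifest(names: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


def seven_feature_manifest() -> list[str]:
    """The shipped seven-feature low-dimensional ACP model manifest."""
    ref = resources.files("acpkit").joinpath("data/acp7d.manifest")
    names = []
    for line in ref.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names
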