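"""Synthetic labelled peptide datasets with controllable class signal.

The generator emulates the shape of the standard anticancer-peptide
benchmark: short peptides of 5-30 residues, an imbalanced 138:206
positive:negative split, and a positive class whose residue composition
is tilted toward a designated residue set (default {K, R, L, G, C} —
lysine, arginine, leucine, glycine, cysteine, the residues whose
composition discriminates ACPs).  Residues are sampled independently;
``bias`` controls how strongly the positive class mixes the tilt set
into the uniform background:

    P_pos(residue) = (uniform + bias · uniform-over-tilt) / (1 + bias)

so ``bias=0`` makes the two classes exchangeable (a null dataset) and
larger values plant a stronger amino-acid-composition signal whose
ground-truth informative features are known (:func:`planted_truth`).

An optional motif mode additionally plants a gapped residue pair
(default G…L with 4 intervening residues, a k-spaced pair signal) in
positive sequences, for exercising gap-pair encoders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import FeatureName
from .sequence_io import ALPHABET, AcpkitError, LabeledDataset, Peptide, write_fasta


class GeneratorError(AcpkitError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the benchmark shape: 138 positives vs 206 negatives,
    lengths uniform on [5, 30], tilt set {K, R, L, G, C}.
    """

    n_pos: int = 138
    n_neg: int = 206
    length_range: tuple[int, int] = (5, 30)
    bias: float = 1.0
    tilt: tuple[str, ...] = ("K", "R", "L", "G", "C")
    seed: int = 0
    motif: tuple[str, str, int] | None = None  # (residue a, residue b, gap)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise GeneratorError(f"invalid length range {self.length_range}")
        if self.bias < 0:
            raise GeneratorError("bias must be >= 0")
        bad = [r for r in self.tilt if r not in ALPHABET]
        if bad:
            raise GeneratorError(f"tilt residues outside alphabet: {bad}")
        if self.motif is not None:
            a, b, gap = self.motif
            if a not in ALPHABET or b not in ALPHABET or gap < 0:
                raise GeneratorError(f"invalid motif {self.motif}")


def _class_probs(config: GeneratorConfig, positive: bool) -> np.ndarray:
    background = np.full(20, 1.0 / 20)
    if not positive or config.bias == 0:
        return background
    tilt = np.zeros(20)
    for residue in config.tilt:
        tilt[ALPHABET.index(residue)] = 1.0 / len(config.tilt)
    return (background + config.bias * tilt) / (1.0 + config.bias)


def generate(config: GeneratorConfig) -> LabeledDataset:
    """Draw a labelled dataset; fully reproducible from ``config.seed``."""
    if config.n_pos + config.n_neg < 2:
        raise GeneratorError("need at least 2 peptides")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    peptides: list[Peptide] = []
    labels: list[int] = []
    for label, count, prefix in ((1, config.n_pos, "pos"),
                                 (0, config.n_neg, "neg")):
        probs = _class_probs(config, positive=bool(label))
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            residues = rng.choice(20, size=length, p=probs)
            seq = list(ALPHABET[r] for r in residues)
            if label and config.motif is not None:
                a, b, gap = config.motif
                span = gap + 2
                if length >= span:
                    start = int(rng.integers(0, length - span + 1))
                    seq[start] = a
                    seq[start + gap + 1] = b
            peptides.append(
                Peptide(id=f"{prefix}_{i + 1:04d}", sequence="".join(seq))
            )
            labels.append(label)
    return LabeledDataset(peptides=peptides, labels=np.array(labels))


def planted_truth(config: GeneratorConfig) -> list[str]:
    """Ground-truth informative feature names for a biased configuration.

    Returns the single-residue composition (AAC) feature names of the
    tilt-set residues — the features a selection procedure should
    recover.  With the motif mode on, the planted gap-pair feature is
    appended.  Raises when ``bias=0`` and no motif is planted (no truth
    exists).
    """
    names: list[str] = []
    if config.bias > 0:
        names += [FeatureName("AAC", (r,)).render() for r in config.tilt]
    if config.motif is not None:
        a, b, gap = config.motif
        names.append(FeatureName("CKSAAP", (a, b, gap)).render())
    if not names:
        raise GeneratorError("bias=0 and no motif: no planted truth exists")
    return names


def write_two_fasta(
    dataset: LabeledDataset, pos_path: str | Path, neg_path: str | Path
) -> None:
    """Write the standard positives/negatives FASTA pair."""
    pos = [p for p, lab in zip(dataset.peptides, dataset.labels) if lab == 1]
    neg = [p for p, lab in zip(dataset.peptides, dataset.labels) if lab == 0]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
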