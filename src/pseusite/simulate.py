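"""Synthetic uridine-centred windows with position-specific enrichment.

Real Ψ-site benchmarks show position-specific nucleotide preferences around
the central uridine — in the human data, A and U are enriched at +1 in
modified sequences while unmodified ones prefer C and G there.  The
generator emulates exactly that class-discriminating structure: each
position is drawn independently from a class-conditional distribution (an
enrichment map where one is given, a shared background elsewhere) and the
centre is always U.  Classes are balanced by default, like the benchmarks.

An optional first-order Markov blending (``markov``) correlates adjacent
bases so that dinucleotide/trinucleotide features carry signal beyond the
positional marginals.  What the generator deliberately does *not* imitate:
the composition statistics, GC content or redundancy structure of any real
transcriptome — pipeline accuracy on these fixtures demonstrates method
correctness, not biological performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .encoders import BASES
from .io import RnaSequenceRecord, SequenceDataset

U = BASES.index("U")

ProbVec = tuple[float, float, float, float]  # over A, C, G, U
UNIFORM: ProbVec = (0.25, 0.25, 0.25, 0.25)


def _check_probs(p: Sequence[float], where: str) -> np.ndarray:
    arr = np.asarray(p, dtype=np.float64)
    if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{where}: not a probability 4-vector over A/C/G/U: {p}")
    return arr


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``enrichment`` maps a centre-relative offset (+1 = immediately 3' of
    the centre U) to a pair of distributions (positive class, negative
    class); unmapped offsets use ``background`` for both classes.
    """

    window_length: int = 21
    n_pos: int = 200
    n_neg: int = 200
    enrichment: Mapping[int, tuple[ProbVec, ProbVec]] = field(default_factory=dict)
    background: ProbVec = UNIFORM
    markov: float = 0.0  # blend weight toward repeating the previous base
    seed: int = 0

    def __post_init__(self) -> None:
        lam = self.window_length
        if lam < 1 or lam % 2 == 0:
            raise ValueError(f"window length must be a positive odd integer, got {lam}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be nonnegative")
        if not 0.0 <= self.markov < 1.0:
            raise ValueError("markov must be in [0, 1)")
        half = (lam - 1) // 2
        _check_probs(self.background, "background")
        for off, (p_pos, p_neg) in self.enrichment.items():
            if off == 0:
                raise ValueError("offset 0 is the centre U and cannot be enriched")
            if abs(off) > half:
                raise ValueError(f"offset {off} outside the ±{half} window")
            _check_probs(p_pos, f"positive class at offset {off:+d}")
            _check_probs(p_neg, f"negative class at offset {off:+d}")

    def class_probs(self, label: int) -> np.ndarray:
        """λ×4 per-position distributions for one class (centre row is δ_U)."""
        lam = self.window_length
        half = (lam - 1) // 2
        probs = np.tile(np.asarray(self.background), (lam, 1))
        for off, pair in self.enrichment.items():
            probs[half + off] = pair[0 if label == 1 else 1]
        probs[half] = 0.0
        probs[half, U] = 1.0
        return probs


def generate(spec: SyntheticSpec, seed: int | None = None) -> SequenceDataset:
    """Draw n_pos positive + n_neg negative windows; deterministic per seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[RnaSequenceRecord] = []
    half = (spec.window_length - 1) // 2
    for label, count, tag in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        probs = spec.class_probs(label)
        codes = np.empty((count, spec.window_length), dtype=int)
        if spec.markov == 0.0:
            for pos in range(spec.window_length):
                codes[:, pos] = rng.choice(4, size=count, p=probs[pos])
        else:
            for i in range(count):
                for pos in range(spec.window_length):
                    p = probs[pos]
                    if pos > 0 and pos != half:
                        p = (1.0 - spec.markov) * p.copy()
                        p[codes[i, pos - 1]] += spec.markov
                    codes[i, pos] = rng.choice(4, p=p)
        for i in range(count):
            seq = "".join(BASES[c] for c in codes[i])
            records.append(RnaSequenceRecord(id=f"{tag}_{i + 1}", sequence=seq, label=label))
    return SequenceDataset(records, center_check=True)


def _biased(favored: str, strength: float) -> ProbVec:
    """Distribution putting ``strength`` on each of two favored bases."""
    rest = (1.0 - 2.0 * strength) / 2.0
    return tuple(strength if b in favored else rest for b in BASES)  # type: ignore[return-value]


def default_specs(
    n_pos: int = 200, n_neg: int = 200, strength: float = 0.45, seed: int = 0
) -> dict[str, SyntheticSpec]:
    """Named presets with fictitious but realistically shaped enrichment.

    * ``human-like`` (λ=21): positives A/U-rich and negatives C/G-rich at
      offsets ±1 and ±2 — strong near-centre enrichment echoing the A/U
      versus C/G contrast at +1 seen in the human benchmark.
    * ``yeast-like`` (λ=31): positives U/G-rich upstream (−3..−1) and
      G/C-rich downstream (+1..+3) against a uniform negative class.
    * ``null`` (λ=21): no enrichment anywhere — classes are statistically
      identical, so any predictor should sit at chance.
    """
    au_cg = (_biased("AU", strength), _biased("CG", strength))
    human = SyntheticSpec(
        window_length=21, n_pos=n_pos, n_neg=n_neg,
        enrichment={-2: au_cg, -1: au_cg, 1: au_cg, 2: au_cg},
        seed=seed,
    )
    yeast = SyntheticSpec(
        window_length=31, n_pos=n_pos, n_neg=n_neg,
        enrichment={
            **{off: (_biased("UG", strength), UNIFORM) for off in (-3, -2, -1)},
            **{off: (_biased("GC", strength), UNIFORM) for off in (1, 2, 3)},
        },
        seed=seed,
    )
    null = SyntheticSpec(window_length=21, n_pos=n_pos, n_neg=n_neg, seed=seed)
    return {"human-like": human, "yeast-like": yeast, "null": null}
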