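"""Synthetic siRNA-mRNA datasets with a planted efficacy model.

The generator draws a pool of random transcripts, cuts random 19-nt windows,
and emits guides as their reverse complements (so every record has a binding
site by construction) with random 2-nt 3' overhangs. Observed efficacy is a
planted noisy linear function of named features from the package's own
quantitative and qualitative representations, rescaled affinely into
[0, 100]. Because the plant is expressed in the artifact's own feature space,
recovery experiments test the pipeline's statistical behavior, not biological
truth.

Effect weights apply to z-scored feature columns (so a unit weight means a
unit-variance contribution regardless of the feature's natural scale), and
``noise_sd`` is Gaussian noise on the same scale: ``noise_sd = 1`` makes the
noise as strong as one planted unit-weight feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import qual_features, quant_features
from .featurize import featurize_records
from .sequence_io import CORE_LENGTH, SirnaRecord, reverse_complement

#: planted signal split across both representations: quantitative stacking
#: energies and target-composition features, and qualitative positional
#: rule/sequence codes. The quantitative plants are deliberately weakly
#: inter-correlated (individual stacks, specific trinucleotides) so that
#: ranking-recovery experiments are well-posed; summary features like G% or
#: ΔG_duplex have too many near-collinear surrogates to be identifiable.
DEFAULT_EFFECT_WEIGHTS: dict[str, float] = {
    # guide stacking energies at mutually disjoint core positions
    "ΔG position 2-3": 2.0,
    "ΔG position 5-6": -2.0,
    "ΔG position 8-9": 2.0,
    "ΔG position 11-12": -2.0,
    "ΔG position 14-15": 2.0,
    "ΔG position 17-18": -2.0,
    # target trinucleotides in anagram pairs with opposite signs, so mono-
    # nucleotide summaries of the same mRNA carry no aggregate signal
    "ACG% of mRNA": 2.0,
    "GCA% of mRNA": -2.0,
    "AAU% of neighbourhood": 2.0,
    "UUC% of neighbourhood": -2.0,
    # qualitative: rule codes and a one-hot channel at loci the stacks avoid
    "rule pos1": 1.0,
    "rule pos13": 1.0,
    "rule pos19": 1.0,
    "pos7=A": 1.0,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one synthetic dataset draw."""

    n_records: int = 500
    mrna_length: int = 500
    gc_content: float = 0.5
    effect_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    noise_sd: float = 1.0
    seed: int = 0
    n_targets: int | None = None  # default: ~1 target per 10 records
    window: int = 20
    #: fraction of records rescaled to land at or above the 70% activity
    #: threshold; None maps the full range onto [2, 98] instead
    active_fraction: float | None = 0.3


def simulate_mrna(length: int, gc_content: float, rng: np.random.Generator | int) -> str:
    """An i.i.d. random transcript with the requested GC content."""
    if length < 25:
        raise ValueError(f"mRNA length must be >= 25, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p_gc = gc_content / 2.0
    p_au = (1.0 - gc_content) / 2.0
    return "".join(rng.choice(list("ACGU"), size=length, p=[p_au, p_gc, p_gc, p_au]))


def _zscore_columns(matrix: np.ndarray, cols: list[int]) -> np.ndarray:
    out = np.empty((matrix.shape[0], len(cols)))
    for j, c in enumerate(cols):
        col = matrix[:, c]
        sd = col.std()
        if sd == 0:
            raise ValueError(
                "planted effect feature is constant over the generated records; "
                "it cannot carry signal"
            )
        out[:, j] = (col - col.mean()) / sd
    return out


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[SirnaRecord], dict[str, str], dict]:
    """Draw records, their target mRNAs, and the planted truth.

    Returns ``(records, mrnas, truth)`` where ``truth`` records the planted
    weights, the noiseless linear predictor, the noisy predictor actually
    rescaled into the efficacies, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_targets = spec.n_targets or max(1, spec.n_records // 10)

    mrnas = {
        f"T{i:03d}": simulate_mrna(spec.mrna_length, spec.gc_content, rng)
        for i in range(n_targets)
    }
    target_ids = list(mrnas)

    records: list[SirnaRecord] = []
    for i in range(spec.n_records):
        tid = target_ids[int(rng.integers(n_targets))]
        mrna = mrnas[tid]
        start = int(rng.integers(0, len(mrna) - CORE_LENGTH + 1))
        core = reverse_complement(mrna[start: start + CORE_LENGTH])
        overhang = "".join(rng.choice(list("ACGU"), size=2))
        records.append(
            SirnaRecord(
                id=f"s{i:04d}", guide=core + overhang, target_id=tid,
                efficacy=None, site_start=start,
            )
        )

    quant, qual = featurize_records(records, mrnas, window=spec.window)
    name_to_col = {name: ("quant", i) for i, name in enumerate(quant_features.feature_names())}
    name_to_col.update(
        {name: ("qual", i) for i, name in enumerate(qual_features.qual_feature_names())}
    )
    unknown = [n for n in spec.effect_weights if n not in name_to_col]
    if unknown:
        raise ValueError(f"unknown effect feature names: {unknown}")

    weights = np.array([spec.effect_weights[n] for n in spec.effect_weights])
    cols = []
    for name in spec.effect_weights:
        which, idx = name_to_col[name]
        cols.append((quant if which == "quant" else qual)[:, idx])
    design = _zscore_columns(np.column_stack(cols), list(range(len(cols))))
    predictor = design @ weights
    noisy = predictor + rng.normal(0.0, spec.noise_sd, size=spec.n_records)

    lo, hi = noisy.min(), noisy.max()
    if hi == lo:
        raise ValueError("degenerate planted predictor: all records identical")
    if spec.active_fraction is None:
        scale = 96.0 / (hi - lo)
        offset = 2.0 - scale * lo
    else:
        anchor = np.quantile(noisy, 1.0 - spec.active_fraction)
        scale = min(
            28.0 / max(hi - anchor, 1e-12), 68.0 / max(anchor - lo, 1e-12)
        )
        offset = 70.0 - scale * anchor
    efficacies = np.clip(scale * noisy + offset, 0.0, 100.0)

    records = [
        SirnaRecord(
            id=r.id, guide=r.guide, target_id=r.target_id,
            efficacy=float(e), site_start=r.site_start,
        )
        for r, e in zip(records, efficacies)
    ]
    truth = {
        "weights": dict(spec.effect_weights),
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "predictor": predictor,
        "noisy_predictor": noisy,
        "scale": float(scale),
        "offset": float(offset),
    }
    return records, mrnas, truth
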