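"""Turn siRNA records plus target mRNAs into the two feature matrices."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import quant_features, qual_features
from .qual_features import RuleTable
from .sequence_io import SirnaRecord, locate_binding_site
from .thermo import EnergyCache, NearestNeighborTable, interaction_energies, thermo_profile


def featurize_records(
    records: Sequence[SirnaRecord],
    mrnas: Mapping[str, str],
    window: int = 20,
    backend: str = "fallback",
    params: NearestNeighborTable | None = None,
    rule_table: RuleTable | None = None,
    cache: EnergyCache | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n x 275) quantitative and (n x 103) qualitative matrices.

    Each record is located on its target (explicit ``site_start`` wins over
    sequence search), its stability profile and interaction energies computed
    with the given backend, and both representations assembled row-per-record.
    """
    quant_rows, qual_rows = [], []
    for record in records:
        try:
            mrna = mrnas[record.target_id]
        except KeyError:
            raise KeyError(
                f"record {record.id!r}: no mRNA sequence for target "
                f"{record.target_id!r}"
            ) from None
        context = locate_binding_site(record, mrna, window=window)
        profile = thermo_profile(record.core, params)
        interact = interaction_energies(
            record, context, backend=backend, params=params, cache=cache
        )
        quant_rows.append(
            quant_features.build_quant_vector(record, context, profile, interact)
        )
        qual_rows.append(qual_features.build_qual_vector(record.guide, rule_table))
    return np.asarray(quant_rows), np.asarray(qual_rows)


def feature_frame(
    records: Sequence[SirnaRecord],
    mrnas: Mapping[str, str],
    representation: str = "quant",
    **kwargs,
) -> pd.DataFrame:
    """One representation as a DataFrame (records x named features),
    with observed efficacy appended when present."""
    quant, qual = featurize_records(records, mrnas, **kwargs)
    if representation == "quant":
        frame = pd.DataFrame(quant, columns=quant_features.feature_names())
    elif representation == "qual":
        frame = pd.DataFrame(qual, columns=qual_features.qual_feature_names())
    else:
        raise ValueError(f"unknown representation {representation!r}")
    frame.index = pd.Index([r.id for r in records], name="id")
    if all(r.efficacy is not None for r in records):
        frame["efficacy"] = [r.efficacy for r in records]
    return frame
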