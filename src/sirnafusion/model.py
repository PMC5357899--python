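"""Model/Results interface tying the whole pipeline together.

``SirnaEfficacyModel`` is constructed from siRNA records plus their target
mRNAs (featurization happens up front); ``fit()`` runs F-score feature
selection over the quantitative representation followed by two-stage SVR
score-level fusion, and returns a ``SirnaEfficacyResults`` carrying the fitted
fusion model, the selection trace, cross-validated diagnostics and a
``summary()`` table. Prediction on new records goes through the same
featurization with the stored configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qual_features, quant_features
from .evaluation import EvaluationReport, evaluate_predictions, pearson
from .featurize import featurize_records
from .feature_selection import (
    FScoreReport,
    SelectionResult,
    apply_selection,
    binarize_labels,
    binary_search_subset,
    f_score,
)
from .fusion import FusionModel, out_of_fold_scores, train_fusion
from .qual_features import RuleTable
from .sequence_io import SirnaRecord, parse_fasta, parse_sirna_table
from .thermo import EnergyCache, NearestNeighborTable


class SirnaEfficacyModel:
    """siRNA knockdown-efficacy model over dual representations.

    Parameters
    ----------
    records : sequence of SirnaRecord
        Labeled training records (efficacy in [0, 100]).
    mrnas : mapping of target_id -> RNA sequence
        Every record's target must be present.
    window : int
        Neighborhood half-width around the binding site, nt.
    backend : {"fallback", "rnaup"}
        Interaction-energy backend (see :mod:`sirnafusion.thermo`).
    """

    def __init__(
        self,
        records: Sequence[SirnaRecord],
        mrnas: Mapping[str, str],
        window: int = 20,
        backend: str = "fallback",
        params: NearestNeighborTable | None = None,
        rule_table: RuleTable | None = None,
        cache: EnergyCache | None = None,
    ):
        if not records:
            raise ValueError("no records given")
        missing = [r.id for r in records if r.efficacy is None]
        if missing:
            raise ValueError(f"records without efficacy labels: {missing[:5]}")
        self.records = list(records)
        self.mrnas = dict(mrnas)
        self.config = {
            "window": window,
            "backend": backend,
        }
        self._params = params
        self._rule_table = rule_table
        self._cache = cache
        self.endog = np.array([r.efficacy for r in records], dtype=float)
        self.exog_quant, self.exog_qual = featurize_records(
            records, mrnas, window=window, backend=backend,
            params=params, rule_table=rule_table, cache=cache,
        )
        self.quant_names = quant_features.feature_names()
        self.qual_names = qual_features.qual_feature_names()

    @classmethod
    def from_tables(
        cls, sirna_table: str | Path, mrna_fasta: str | Path, **kwargs
    ) -> "SirnaEfficacyModel":
        """Build from the standard record TSV and mRNA FASTA files."""
        return cls(parse_sirna_table(sirna_table), parse_fasta(mrna_fasta), **kwargs)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, mrnas: Mapping[str, str], **kwargs
    ) -> "SirnaEfficacyModel":
        """Build from a DataFrame with columns id, guide, target_id, efficacy."""
        records = [
            SirnaRecord(
                id=str(row["id"]),
                guide=row["guide"],
                target_id=str(row["target_id"]),
                efficacy=float(row["efficacy"]) if "efficacy" in row and
                pd.notna(row["efficacy"]) else None,
                site_start=int(row["site_start"]) - 1
                if "site_start" in row and pd.notna(row.get("site_start")) else None,
            )
            for _, row in frame.iterrows()
        ]
        return cls(records, mrnas, **kwargs)

    def _selection_evaluator(self, report: FScoreReport, n_folds: int, seed: int):
        """Score a top-k subset by cross-validated PCC of a linear SVR."""
        y = self.endog

        def evaluate(k: int) -> float:
            columns = report.top(k)
            X = apply_selection(self.exog_quant, columns)
            oof = out_of_fold_scores(
                X, y, kernel="linear", k=n_folds, seed=seed, standardize=True
            )
            return pearson(oof, y)

        return evaluate

    def fit(
        self,
        select: bool = True,
        kernels: tuple[str, str, str] = ("linear", "rbf", "linear"),
        hyper: dict | None = None,
        n_folds: int = 10,
        selection_folds: int = 5,
        seed: int = 0,
    ) -> "SirnaEfficacyResults":
        """Select quantitative features and fit the two-stage fusion model.

        ``select=False`` skips selection and uses all 275 quantitative
        features. Subset sizes are scored by ``selection_folds``-fold
        cross-validated PCC of a linear SVR over active/inactive-labeled
        training data per the F-score ranking.
        """
        fscore_report = None
        selection = None
        if select:
            labels = binarize_labels(self.endog)
            fscore_report = f_score(self.exog_quant, labels, names=self.quant_names)
            selection = binary_search_subset(
                fscore_report.ranking,
                self._selection_evaluator(fscore_report, selection_folds, seed),
            )
            selected = selection.selected_indices
        else:
            selected = np.arange(self.exog_quant.shape[1])

        fusion = train_fusion(
            self.exog_quant,
            self.exog_qual,
            self.endog,
            selected_indices=selected,
            kernels=kernels,
            hyper=hyper,
            n_folds=n_folds,
            seed=seed,
        )
        return SirnaEfficacyResults(self, fusion, fscore_report, selection)


class SirnaEfficacyResults:
    """Fitted efficacy model: estimates, diagnostics, prediction, summary."""

    def __init__(
        self,
        model: SirnaEfficacyModel,
        fusion: FusionModel,
        fscore_report: FScoreReport | None,
        selection: SelectionResult | None,
    ):
        self.model = model
        self.fusion = fusion
        self.fscore_report = fscore_report
        self.selection = selection
        self.fittedvalues = fusion.predict(model.exog_quant, model.exog_qual)
        oof = np.asarray(fusion.metadata["oof_scores"])
        #: out-of-fold stage-1 scores used to train stage 2 (n x 2)
        self.oof_scores = oof
        self.branch_pcc = {
            "quant": pearson(oof[:, 0], model.endog),
            "qual": pearson(oof[:, 1], model.endog),
        }

    @property
    def selected_names(self) -> list[str]:
        idx = self.fusion.selected_indices
        return [self.model.quant_names[i] for i in idx]

    def _featurize(self, records, mrnas=None):
        mrnas = mrnas if mrnas is not None else self.model.mrnas
        return featurize_records(
            records, mrnas,
            window=self.model.config["window"],
            backend=self.model.config["backend"],
            params=self.model._params,
            rule_table=self.model._rule_table,
            cache=self.model._cache,
        )

    def predict(
        self,
        records: Sequence[SirnaRecord] | None = None,
        mrnas: Mapping[str, str] | None = None,
    ) -> np.ndarray:
        """Fused efficacy predictions; with no arguments, the fitted values."""
        if records is None:
            return self.fittedvalues.copy()
        quant, qual = self._featurize(records, mrnas)
        return self.fusion.predict(quant, qual)

    def evaluate(
        self,
        records: Sequence[SirnaRecord],
        mrnas: Mapping[str, str] | None = None,
        spec_targets: Sequence[float] = (0.907, 0.969, 0.99),
    ) -> EvaluationReport:
        """Held-out evaluation: PCC plus ROC/AUC and operating points at the
        70% activity threshold."""
        observed = np.array([r.efficacy for r in records], dtype=float)
        predicted = self.predict(records, mrnas)
        return evaluate_predictions(predicted, observed, spec_targets)

    def save(self, path: str | Path) -> None:
        """Persist the fusion bundle plus a selection manifest."""
        path = Path(path)
        self.fusion.save(path)
        manifest = {
            "selected_names": self.selected_names,
            "config": self.model.config,
        }
        if self.selection is not None:
            manifest["selection_trace"] = [list(t) for t in self.selection.trace]
            manifest["best_score"] = self.selection.best_score
        if self.fscore_report is not None:
            manifest["f_scores"] = {
                name: (None if not np.isfinite(s) else float(s))
                for name, s in zip(self.fscore_report.names,
                                   self.fscore_report.f_scores)
            }
        (path / "selection.json").write_text(json.dumps(manifest, indent=1))

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        m = self.model
        lines = [
            "siRNA Efficacy Fusion Model",
            "=" * 60,
            f"records:                  {len(m.records)}",
            f"targets:                  {len(m.mrnas)}",
            f"quantitative features:    {m.exog_quant.shape[1]}",
            f"qualitative features:     {m.exog_qual.shape[1]}",
            f"selected subset size:     {len(self.fusion.selected_indices)}",
            f"kernels (Qt, Ql, fusion): "
            f"{', '.join(self.fusion.metadata['kernels'])}",
            f"CV folds / seed:          {self.fusion.metadata['n_folds']} / "
            f"{self.fusion.metadata['seed']}",
            "-" * 60,
            f"out-of-fold PCC, quantitative branch:  "
            f"{self.branch_pcc['quant']:.3f}",
            f"out-of-fold PCC, qualitative branch:   "
            f"{self.branch_pcc['qual']:.3f}",
            f"in-sample PCC, fused:                  "
            f"{pearson(self.fittedvalues, m.endog):.3f}",
        ]
        if self.selection is not None:
            sizes = ", ".join(str(k) for _, k, _ in self.selection.trace)
            lines += [
                "-" * 60,
                f"subset search visited sizes: {sizes}",
                f"best subset CV PCC:          {self.selection.best_score:.3f}",
            ]
        top = self.selected_names[:10]
        lines += ["-" * 60, "top selected features: " + ", ".join(top)]
        return "\n".join(lines)
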