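"""Model/Results interface tying the imputation pipeline together.

:class:`MethylationImputer` is constructed from a beta matrix (and optional
probe annotation and sample grouping); ``fit()`` runs the full pipeline —
sample-group split, chromosome split, pattern grouping, logit-space
regression, optional mini-batch — and returns an
:class:`ImputationResults` carrying the imputed matrix, per-chromosome
reports and a text ``summary()``.
"""

from __future__ import annotations

import pandas as pd

from .core import ImputationConfig, ImputationReport, MiniBatchConfig, impute_matrix
from .evaluate import EvaluationResult, evaluate
from .io import BetaMatrix, ProbeAnnotation, SampleGrouping
from .parallel import impute_by_chromosome, merge_sample_groups, split_by_sample_group

__all__ = ["MethylationImputer", "ImputationResults"]


class MethylationImputer:
    """Logit-space regression imputer for a beta-value matrix.

    Parameters
    ----------
    data
        The samples x probes :class:`BetaMatrix` with missing entries.
    annotation
        Optional probe -> chromosome mapping. When given, each chromosome is
        imputed from its own probes (and may run in parallel); when absent
        the whole matrix forms one regression block.
    sample_groups
        Optional sample -> group labels; groups are imputed independently.
    config
        Numerical settings; see :class:`~betaimpute.core.ImputationConfig`.
    """

    def __init__(
        self,
        data: BetaMatrix,
        annotation: ProbeAnnotation | None = None,
        sample_groups: SampleGrouping | None = None,
        config: ImputationConfig | None = None,
    ) -> None:
        data.validate_range()
        self.data = data
        self.annotation = annotation
        self.sample_groups = sample_groups
        self.config = config or ImputationConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        annotation: ProbeAnnotation | None = None,
        sample_groups: SampleGrouping | None = None,
        config: ImputationConfig | None = None,
    ) -> "MethylationImputer":
        """Build from a samples x probes DataFrame (index = sample ids)."""
        return cls(BetaMatrix.from_dataframe(frame), annotation, sample_groups, config)

    def fit(
        self,
        workers: int = 1,
        minibatch_percent: float | None = None,
        minibatch_reps: int = 1,
        seed: int | None = None,
        unannotated_policy: str = "own_group",
    ) -> "ImputationResults":
        """Impute all missing entries and return the results object."""
        config = self.config
        if seed is not None:
            config = config.with_seed(seed)
        if minibatch_percent is not None:
            from dataclasses import replace

            config = replace(
                config,
                minibatch=MiniBatchConfig(
                    percent=minibatch_percent, repetitions=minibatch_reps
                ),
            )

        def _run(part: BetaMatrix) -> tuple[BetaMatrix, dict[str, ImputationReport]]:
            if self.annotation is not None:
                return impute_by_chromosome(
                    part, self.annotation, config, workers, unannotated_policy
                )
            imputed, report = impute_matrix(part, config)
            return imputed, {"all": report}

        if self.sample_groups is not None:
            parts = split_by_sample_group(self.data, self.sample_groups)
            imputed_parts: dict[str, BetaMatrix] = {}
            reports: dict[str, dict[str, ImputationReport]] = {}
            for label, part in parts.items():
                imputed_parts[label], reports[label] = _run(part)
            imputed = merge_sample_groups(self.data, imputed_parts)
        else:
            imputed, flat = _run(self.data)
            reports = {"all": flat}
        return ImputationResults(self, imputed, reports, config)


class ImputationResults:
    """Fitted imputation: the completed matrix plus diagnostics.

    Attributes
    ----------
    imputed
        The :class:`BetaMatrix` with missing entries filled in (entries of
        unimputable groups remain missing).
    reports
        Nested mapping sample-group label -> chromosome label ->
        :class:`~betaimpute.core.ImputationReport`.
    """

    def __init__(
        self,
        model: MethylationImputer,
        imputed: BetaMatrix,
        reports: dict[str, dict[str, ImputationReport]],
        config: ImputationConfig,
    ) -> None:
        self.model = model
        self.imputed = imputed
        self.reports = reports
        self.config = config

    # -- diagnostics -------------------------------------------------------

    @property
    def n_imputed(self) -> int:
        return sum(
            rep.n_imputed_entries
            for by_chrom in self.reports.values()
            for rep in by_chrom.values()
        )

    @property
    def n_remaining_missing(self) -> int:
        return self.imputed.n_missing

    def report_frame(self) -> pd.DataFrame:
        """Per-(group, chromosome) diagnostics as a DataFrame."""
        rows = []
        for glabel, by_chrom in self.reports.items():
            for clabel, rep in by_chrom.items():
                rows.append(
                    {
                        "sample_group": glabel,
                        "chromosome": clabel,
                        "n_pattern_groups": rep.n_groups,
                        "n_imputed_entries": rep.n_imputed_entries,
                        "n_unimputable_groups": rep.n_unimputable_groups,
                    }
                )
        return pd.DataFrame(rows)

    def evaluate_against(
        self, complete: BetaMatrix, mask: list[tuple[int, int]]
    ) -> EvaluationResult:
        """Score the fit against ground truth on the given mask positions."""
        return evaluate(complete, self.imputed, mask)

    def to_dataframe(self) -> pd.DataFrame:
        return self.imputed.to_dataframe()

    def summary(self) -> str:
        """Human-readable account of what was imputed."""
        X = self.model.data
        mb = self.config.minibatch
        lines = [
            "Beta-value imputation results",
            "=" * 45,
            f"samples x probes        {X.n_samples} x {X.n_probes}",
            f"missing entries (input) {X.n_missing}",
            f"imputed entries         {self.n_imputed}",
            f"still missing           {self.n_remaining_missing}",
            f"seed                    {self.config.seed}",
            f"logit eps               {self.config.logit_eps:g}",
            "mini-batch              "
            + (f"P={mb.percent:g}%, R={mb.repetitions}" if mb else "off"),
            "",
            "per-part pattern groups:",
        ]
        frame = self.report_frame()
        lines.append(frame.to_string(index=False) if len(frame) else "  (none)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ImputationResults: {self.n_imputed} imputed, "
            f"{self.n_remaining_missing} still missing>"
        )
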