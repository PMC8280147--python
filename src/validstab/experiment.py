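"""The stability harness.

Replicates a validation regimen across many seeds with the data partitions
held consistent across classifiers, then summarizes each classifier's AUC
distribution: the extreme seeds, their DeLong confidence intervals, the
max-minus-min range, and a non-directional independent-ROC z-test between
the extreme seeds' pooled predictions. Although the extreme prediction
sets come from overlapping pools of the same data, seed variation makes
them unpairable, so they are treated as independent samples; reports carry
a caveat to that effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .regimens import ClassifierContract, RegimenResult, run_regimen
from .roc_stats import AucEstimate, RocComparison, delong_ci, independent_roc_test

logger = logging.getLogger(__name__)

INDEPENDENCE_CAVEAT = (
    "max/min prediction sets overlap in underlying data but are treated as "
    "independent samples"
)


@dataclass
class StabilityReport:
    """Per-(regimen, classifier) summary over all seeds."""

    regimen: str
    classifier: str
    n_seeds: int
    seeds: list[int]
    aucs: np.ndarray
    max_auc: float
    min_auc: float
    range: float
    max_seed: int | None
    min_seed: int | None
    ci_max: AucEstimate | None
    ci_min: AucEstimate | None
    comparison: RocComparison | None
    significance: str  # "ns", "p<0.05", "p<0.01"
    failed_seeds: list[int] = field(default_factory=list)
    caveat: str = INDEPENDENCE_CAVEAT
    max_result: RegimenResult | None = None
    min_result: RegimenResult | None = None

    def to_json_dict(self) -> dict:
        d = {
            "regimen": self.regimen,
            "classifier": self.classifier,
            "n_seeds": self.n_seeds,
            "seeds": list(self.seeds),
            "aucs": [float(a) for a in self.aucs],
            "max_auc": self.max_auc,
            "min_auc": self.min_auc,
            "range": self.range,
            "max_seed": self.max_seed,
            "min_seed": self.min_seed,
            "significance": self.significance,
            "failed_seeds": list(self.failed_seeds),
            "caveat": self.caveat,
        }
        for tag, ci in (("ci_max", self.ci_max), ("ci_min", self.ci_min)):
            d[tag] = None if ci is None else {
                "auc": ci.auc, "variance": ci.variance,
                "ci_low": ci.ci_low, "ci_high": ci.ci_high, "level": ci.level,
            }
        d["comparison"] = None if self.comparison is None else {
            "auc_a": self.comparison.auc_a, "auc_b": self.comparison.auc_b,
            "se_a": self.comparison.se_a, "se_b": self.comparison.se_b,
            "z": self.comparison.z, "p_two_sided": self.comparison.p_two_sided,
            "method": self.comparison.method,
        }
        return d


def significance_tag(p: float | None) -> str:
    if p is None:
        return "ns"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def run_stability(
    data: LabeledDataset,
    classifiers: list[ClassifierContract],
    regimen: str,
    n_seeds: int = 100,
    seeds: list[int] | None = None,
    comparison_method: str = "hanley_mcneil",
    max_failure_fraction: float = 0.10,
    **regimen_params,
) -> list[StabilityReport]:
    """Run `regimen` for every (classifier, seed) cell and summarize.

    Seeds default to 0..n_seeds-1. The partition for a given seed depends
    only on (regimen, seed), so every classifier sees identical splits.
    LOO is seed-free: it is run once per classifier with no extremes or
    comparison. A failing (classifier, seed) cell is logged and skipped; a
    classifier with more than `max_failure_fraction` failed seeds aborts
    the run.
    """
    if regimen == "loo":
        reports = []
        for model in classifiers:
            res = run_regimen(data, model, "loo", 0, **regimen_params)
            ci = delong_ci(res.pooled)
            reports.append(
                StabilityReport(
                    regimen="loo",
                    classifier=model.name,
                    n_seeds=1,
                    seeds=[],
                    aucs=np.array([res.auc_value]),
                    max_auc=res.auc_value,
                    min_auc=res.auc_value,
                    range=0.0,
                    max_seed=None,
                    min_seed=None,
                    ci_max=ci,
                    ci_min=ci,
                    comparison=None,
                    significance="ns",
                    max_result=res,
                    min_result=res,
                )
            )
        return reports

    seed_list = list(seeds) if seeds is not None else list(range(n_seeds))
    if len(seed_list) < 1:
        raise ValueError("at least one seed is required")

    reports = []
    for model in classifiers:
        results: dict[int, RegimenResult] = {}
        failed: list[int] = []
        for s in seed_list:
            try:
                results[s] = run_regimen(data, model, regimen, s, **regimen_params)
            except Exception:
                logger.exception("regimen %s failed for %s at seed %d", regimen, model.name, s)
                failed.append(s)
        if len(failed) > max_failure_fraction * len(seed_list):
            raise RuntimeError(
                f"classifier {model.name!r}: {len(failed)}/{len(seed_list)} seeds failed"
            )
        ok_seeds = [s for s in seed_list if s in results]
        aucs = np.array([results[s].auc_value for s in ok_seeds])
        # ties break toward the lowest seed (argmax/argmin return the first hit)
        max_seed = ok_seeds[int(np.argmax(aucs))]
        min_seed = ok_seeds[int(np.argmin(aucs))]
        max_res, min_res = results[max_seed], results[min_seed]
        ci_max = delong_ci(max_res.pooled)
        ci_min = delong_ci(min_res.pooled)
        if len(ok_seeds) >= 2:
            comparison = independent_roc_test(
                max_res.pooled, min_res.pooled, method=comparison_method
            )
            sig = significance_tag(comparison.p_two_sided)
        else:
            comparison, sig = None, "ns"
        reports.append(
            StabilityReport(
                regimen=regimen,
                classifier=model.name,
                n_seeds=len(ok_seeds),
                seeds=ok_seeds,
                aucs=aucs,
                max_auc=float(aucs.max()),
                min_auc=float(aucs.min()),
                range=float(aucs.max() - aucs.min()),
                max_seed=max_seed,
                min_seed=min_seed,
                ci_max=ci_max,
                ci_min=ci_min,
                comparison=comparison,
                significance=sig,
                failed_seeds=failed,
                max_result=max_res,
                min_result=min_res,
            )
        )
    return reports


def _stars(sig: str) -> str:
    return {"p<0.01": "**", "p<0.05": "*", "ns": ""}[sig]


def _cell(auc_value: float, ci: AucEstimate | None, sig: str) -> str:
    if ci is None:
        return f"{auc_value:.3f}{_stars(sig)}"
    return f"{auc_value:.3f} [{ci.ci_low:.3f}-{ci.ci_high:.3f}]{_stars(sig)}"


def summarize_table(reports: list[StabilityReport]) -> pd.DataFrame:
    """Max/min AUC table: rows "Classifier: Max/Min" x regimen columns.

    Cells read "AUC [lo-hi]" with a star suffix (* p<0.05, ** p<0.01) on
    significant max-vs-min comparisons.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    classifiers, regimens = [], []
    for r in reports:
        if r.classifier not in classifiers:
            classifiers.append(r.classifier)
        if r.regimen not in regimens:
            regimens.append(r.regimen)
    rows = {}
    for clf in classifiers:
        for side in ("Max", "Min"):
            rows[f"{clf}: {side}"] = {}
    for r in reports:
        rows[f"{r.classifier}: Max"][r.regimen] = _cell(r.max_auc, r.ci_max, r.significance)
        rows[f"{r.classifier}: Min"][r.regimen] = _cell(r.min_auc, r.ci_min, r.significance)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=regimens)
    table.index.name = "Method"
    return table


def summarize_ranges(reports: list[StabilityReport]) -> pd.DataFrame:
    """Long-format (classifier, regimen, range) table; LOO rows (no range
    defined) are excluded. Ordering is stable by (classifier, regimen)."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = [
        {"classifier": r.classifier, "regimen": r.regimen, "range": r.range}
        for r in reports
        if r.regimen != "loo"
    ]
    frame = pd.DataFrame(rows, columns=["classifier", "regimen", "range"])
    return frame.sort_values(["classifier", "regimen"], kind="stable").reset_index(drop=True)


def auc_matrix(reports: list[StabilityReport]) -> pd.DataFrame:
    """Seed x classifier AUC matrix for one regimen's reports."""
    regs = {r.regimen for r in reports}
    if len(regs) != 1:
        raise ValueError("auc_matrix expects reports from a single regimen")
    cols = {}
    for r in reports:
        idx = r.seeds if r.seeds else [0]
        cols[r.classifier] = pd.Series(r.aucs, index=idx)
    frame = pd.DataFrame(cols)
    frame.index.name = "seed"
    return frame
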