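"""Benchmarking analyses built on the CAPS statistic.

Four analyses, mirroring how deleteriousness filters are used in
variant-prioritisation practice:

* threshold filters and their sequential "chaining";
* top-fraction separation curves (how deleterious are the top f% of
  variants ranked by one tool's score);
* all 1- and 2-filter combination grids, with detection of a single
  "key annotation" that carries the whole signal;
* ClinVar stratification by significance class and review-star tier,
  and calibration of the tools' own classification labels.
"""

from __future__ import annotations

import itertools
import logging
import math
import operator
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .caps import CapsEstimate, ReferenceModel, caps_by_group, compute_caps
from .errors import ConfigurationError, EmptyGroupError
from .tools import HIGHER, LOWER, ToolMeta, score_column

logger = logging.getLogger(__name__)

_COMPARATORS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}


@dataclass(frozen=True)
class FilterSpec:
    """One threshold criterion on one tool's score, e.g. ``REVEL > 0.75``."""

    tool: str
    comparator: str
    threshold: float
    label: str = ""

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.tool} {self.comparator} {self.threshold:g}")

    def validate(self, registry: dict[str, ToolMeta]) -> None:
        if self.tool not in registry:
            raise ConfigurationError(f"filter references unregistered tool {self.tool!r}")
        meta = registry[self.tool]
        deleterious_side = {"<", "<="} if meta.orientation == LOWER else {">", ">="}
        if self.comparator not in deleterious_side:
            raise ConfigurationError(
                f"filter {self.label!r}: comparator {self.comparator!r} points to the "
                f"benign side for a {meta.orientation} tool"
            )

    def mask(self, table: pd.DataFrame) -> pd.Series:
        """Row mask; variants with a missing score fail the criterion."""
        col = score_column(self.tool)
        if col not in table.columns:
            raise ConfigurationError(f"table lacks scores for tool {self.tool!r} ({col})")
        scores = table[col]
        passed = _COMPARATORS[self.comparator](scores, self.threshold) & scores.notna()
        n_missing = int(scores.isna().sum())
        if n_missing:
            logger.info("filter %s: %d variants missing a score fail", self.label, n_missing)
        return passed


def established_filters() -> list[FilterSpec]:
    """The stringent, commonly recommended threshold set."""
    return [
        FilterSpec("SIFT", "<", 0.05),
        FilterSpec("PolyPhen", ">", 0.8),
        FilterSpec("CADD", ">", 20.0),
    ]


def sensitivity95_filters() -> list[FilterSpec]:
    """The lenient set tuned for ~95% sensitivity per tool."""
    return [
        FilterSpec("SIFT", "<", 0.49),
        FilterSpec("PolyPhen", ">", 0.022),
        FilterSpec("CADD", ">", 10.37),
    ]


def apply_filters(
    table: pd.DataFrame,
    specs: Sequence[FilterSpec],
    registry: Optional[dict[str, ToolMeta]] = None,
) -> pd.DataFrame:
    """Conjunction of threshold filters; an empty spec list is the identity."""
    if registry is not None:
        for spec in specs:
            spec.validate(registry)
    keep = pd.Series(True, index=table.index)
    for spec in specs:
        keep &= spec.mask(table)
    return table[keep]


def chain_filters(
    table: pd.DataFrame,
    specs: Sequence[FilterSpec],
    model: ReferenceModel,
    registry: Optional[dict[str, ToolMeta]] = None,
    **caps_kw,
) -> list[CapsEstimate]:
    """CAPS after each step of sequentially added filters.

    Estimate ``i`` describes the conjunction of the first ``i+1``
    filters; variant counts are non-increasing along the chain.  If a
    step empties the table the chain is truncated with a logged step
    index.
    """
    if not specs:
        raise ConfigurationError("chain_filters needs at least one filter")
    if registry is not None:
        for spec in specs:
            spec.validate(registry)
    current = table
    estimates: list[CapsEstimate] = []
    applied: list[str] = []
    for i, spec in enumerate(specs):
        current = current[spec.mask(current)]
        applied.append(spec.label)
        if len(current) == 0:
            logger.warning("chain truncated: step %d (%s) empties the table", i, spec.label)
            break
        estimates.append(compute_caps(current, model, label=" & ".join(applied), **caps_kw))
    return estimates


@dataclass(frozen=True)
class TopFractionScheme:
    """Exponentially spaced top fractions (percent) for separation curves.

    The default halving grid brackets the few-percent regime where the
    best predictors differentiate; ``na_policy`` chooses between
    complete-case removal (drop rows missing any compared tool's score,
    for fair multi-tool comparison) and per-tool removal.
    """

    fractions: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.5625)
    na_policy: str = "complete_case"

    def __post_init__(self):
        fr = self.fractions
        if not fr or any(not 0 < f <= 100 for f in fr):
            raise ConfigurationError("fractions must lie in (0, 100]")
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ConfigurationError("fractions must be strictly decreasing")
        if self.na_policy not in ("complete_case", "per_tool"):
            raise ConfigurationError(f"unknown na_policy {self.na_policy!r}")


def complete_case(table: pd.DataFrame, tools: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Rows with no missing score for any of the given tools (default: all)."""
    if tools is None:
        cols = [c for c in table.columns if c.startswith("score_")]
    else:
        cols = [score_column(t) for t in tools]
    return table.dropna(subset=cols)


def top_fraction_curve(
    table: pd.DataFrame,
    tool: str,
    scheme: TopFractionScheme,
    model: ReferenceModel,
    registry: dict[str, ToolMeta],
    compare_tools: Optional[Sequence[str]] = None,
    **caps_kw,
) -> list[CapsEstimate]:
    """CAPS of the most deleterious f% of variants, for each fraction.

    Variants are ranked orientation-aware (ascending score for
    lower-is-deleterious tools) with ties broken by stable input order;
    the top group holds exactly ``ceil(f * N / 100)`` variants, so the
    100% entry is the whole (complete-case) table.
    """
    if tool not in registry:
        raise ConfigurationError(f"tool {tool!r} not in registry")
    if scheme.na_policy == "complete_case":
        table = complete_case(table, compare_tools)
    else:
        table = table.dropna(subset=[score_column(tool)])
    scores = table[score_column(tool)].to_numpy(dtype=float)
    if registry[tool].orientation == HIGHER:
        order = np.argsort(-scores, kind="stable")
    else:
        order = np.argsort(scores, kind="stable")
    ranked = table.iloc[order]
    N = len(ranked)
    out = []
    for f in scheme.fractions:
        k = math.ceil(f * N / 100.0)
        if k == 0:
            logger.warning("fraction %g%% selects no variants; omitted", f)
            continue
        out.append(
            compute_caps(ranked.iloc[:k], model, label=f"{tool} top {f:g}%", **caps_kw)
        )
    return out


@dataclass
class GridResult:
    """CAPS of every single filter and every unordered filter pair."""

    singles: dict[str, Optional[CapsEstimate]]
    pairs: dict[frozenset, Optional[CapsEstimate]]
    labels: list[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> Optional[CapsEstimate]:
        return self.pairs[frozenset((a, b))]

    def matrix(self) -> pd.DataFrame:
        """Square CAPS matrix (diagonal = singles) for heatmap rendering."""
        m = pd.DataFrame(np.nan, index=self.labels, columns=self.labels)
        for lab, est in self.singles.items():
            if est is not None:
                m.loc[lab, lab] = est.caps
        for key, est in self.pairs.items():
            a, b = sorted(key)
            if est is not None:
                m.loc[a, b] = est.caps
                m.loc[b, a] = est.caps
        return m


def pairwise_filter_grid(
    table: pd.DataFrame,
    specs: Sequence[FilterSpec],
    model: ReferenceModel,
    registry: Optional[dict[str, ToolMeta]] = None,
    **caps_kw,
) -> GridResult:
    """All 1- and 2-filter combinations; empty cells are marked, not errors."""
    if len(specs) < 2:
        raise ConfigurationError("pairwise_filter_grid needs at least two filters")
    if registry is not None:
        for spec in specs:
            spec.validate(registry)
    masks = {spec.label: spec.mask(table) for spec in specs}
    singles: dict[str, Optional[CapsEstimate]] = {}
    for spec in specs:
        sub = table[masks[spec.label]]
        singles[spec.label] = (
            compute_caps(sub, model, label=spec.label, **caps_kw) if len(sub) else None
        )
    pairs: dict[frozenset, Optional[CapsEstimate]] = {}
    for a, b in itertools.combinations(specs, 2):
        sub = table[masks[a.label] & masks[b.label]]
        key = frozenset((a.label, b.label))
        pairs[key] = (
            compute_caps(sub, model, label=f"{a.label} & {b.label}", **caps_kw)
            if len(sub)
            else None
        )
        if pairs[key] is None:
            logger.info("grid cell (%s, %s) is empty", a.label, b.label)
    return GridResult(singles=singles, pairs=pairs, labels=[s.label for s in specs])


def find_key_annotation(grid: GridResult) -> Optional[str]:
    """The single filter that carries the whole deleteriousness signal.

    Returns the filter with the highest single-filter CAPS if every
    pair containing it has a confidence interval overlapping that
    filter's own (adding any other filter neither adds nor removes
    signal); otherwise None.
    """
    candidates = {lab: est for lab, est in grid.singles.items() if est is not None}
    if not candidates:
        return None
    best = max(candidates, key=lambda lab: candidates[lab].caps)
    best_est = candidates[best]
    for other in grid.labels:
        if other == best:
            continue
        pair = grid.pairs.get(frozenset((best, other)))
        if pair is None:
            continue
        if not pair.ci_overlaps(best_est):
            return None
    return best


_MERGE_LIKELY = {"likely_benign": "benign", "likely_pathogenic": "pathogenic"}


def clinvar_strata(
    table: pd.DataFrame,
    model: ReferenceModel,
    merge_likely: bool = True,
    **caps_kw,
) -> list[CapsEstimate]:
    """CAPS per (ClinVar significance class x review-star tier) cell.

    Variants without a ClinVar record are excluded.  With
    ``merge_likely`` the "likely" subclasses fold into their parent
    class.  Records with a significance but no star tier conservatively
    count as 0 stars.
    """
    sig = table.get("clinvar_significance")
    if sig is None:
        raise ConfigurationError("table lacks clinvar_significance")
    labelled = table[sig.notna() & (sig != "absent")]
    if labelled.empty:
        raise EmptyGroupError("no ClinVar-labelled variants in the table")
    cls = labelled["clinvar_significance"].astype(str)
    if merge_likely:
        cls = cls.replace(_MERGE_LIKELY)
    stars = labelled.get("clinvar_stars")
    if stars is None:
        stars = pd.Series(0, index=labelled.index)
    stars = stars.fillna(0).astype(int)
    key = cls + "|" + stars.astype(str) + "*"
    return caps_by_group(labelled, model, key, **caps_kw)


def label_calibration(
    table: pd.DataFrame,
    registry: dict[str, ToolMeta],
    model: ReferenceModel,
    **caps_kw,
) -> list[CapsEstimate]:
    """CAPS of the variants each tool itself labels deleterious.

    For every registered tool with a default threshold, computes CAPS of
    the variant set passing that threshold and attaches the tool's own
    classification word ("Damaging", "Disease causing", ...), so a
    report can contrast what the label claims with the measured average
    deleteriousness.
    """
    estimates = []
    for name in sorted(registry):
        meta = registry[name]
        if meta.default_threshold is None:
            logger.warning("label_calibration: tool %s has no default threshold; skipped", name)
            continue
        if score_column(name) not in table.columns:
            logger.warning("label_calibration: no %s scores on the table; skipped", name)
            continue
        spec = FilterSpec(
            tool=name,
            comparator=meta.deleterious_comparator,
            threshold=meta.default_threshold,
        )
        sub = table[spec.mask(table)]
        if len(sub) == 0:
            logger.warning("label_calibration: no variants pass %s; omitted", spec.label)
            continue
        word = meta.deleterious_label or "deleterious"
        est = compute_caps(sub, model, label=f"{name} [{word}]", **caps_kw)
        est.extra["tool"] = name
        est.extra["deleterious_label"] = word
        est.extra["threshold"] = meta.default_threshold
        estimates.append(est)
    return estimates
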