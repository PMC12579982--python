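"""The CAPS statistic: context-adjusted proportion of singletons.

An excess of singletons (variants with allele count 1) in a group of
SNVs is a signature of negative selection.  The raw proportion of
singletons is confounded by mutation rate, so the expected number of
singletons is taken from per-trinucleotide-context singleton proportions
measured on a near-neutral reference set.  For a group of N variants
with S observed singletons and expected count

    E = sum_c  n_c * p_ref(c)

over its context classes, the statistic is

    CAPS = (S - E) / N

with standard error sqrt(p_hat (1 - p_hat) / N), p_hat = S / N, treating
E as fixed (the reference set is assumed to be much larger than any
query group).  The 95% interval is the normal approximation
CAPS +/- z * SE; a Wilson interval is available for small groups or
p_hat near 0/1.

A simplified MAPS (mutability-adjusted proportion of singletons) is also
provided: the expectation comes from a weighted least-squares regression
of per-context reference singleton proportion on log10 mutability rather
than from the per-context proportions directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    EmptyGroupError,
    MissingContextError,
    ModelConstructionError,
)

logger = logging.getLogger(__name__)

#: A mutability table is a mapping from context-label string to a
#: positive relative mutation rate; stored as a pandas Series.
MutabilityTable = pd.Series


@dataclass
class ReferenceModel:
    """Per-context singleton proportions learned from a reference set.

    ``counts`` is indexed by context-label string with integer columns
    ``n_ref`` and ``s_ref``; ``p_ref`` is always exactly
    ``s_ref / n_ref``.  Contexts absent from the reference are absent
    from the model, and querying them is a hard error.
    """

    counts: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        if self.counts.empty:
            raise ModelConstructionError("reference model has no contexts")
        c = self.counts
        if (c["n_ref"] < 1).any():
            raise ModelConstructionError("every stored context needs n_ref >= 1")
        c["p_ref"] = c["s_ref"] / c["n_ref"]
        c.index.name = "context"

    @classmethod
    def from_table(cls, reference: pd.DataFrame, provenance: str = "") -> "ReferenceModel":
        """Build the model from a QC-filtered, context-assigned variant table."""
        if reference.empty:
            raise ModelConstructionError("empty reference table")
        if "context_label" not in reference.columns:
            raise ModelConstructionError("reference table lacks a context_label column")
        g = reference.groupby("context_label", sort=True)["is_singleton"]
        counts = pd.DataFrame({"n_ref": g.size(), "s_ref": g.sum().astype(np.int64)})
        return cls(counts, provenance=provenance)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, tuple[int, int]], provenance: str = ""
    ) -> "ReferenceModel":
        """Build from explicit ``{context: (n_ref, s_ref)}`` counts."""
        df = pd.DataFrame(
            {
                "n_ref": {k: n for k, (n, _) in counts.items()},
                "s_ref": {k: s for k, (_, s) in counts.items()},
            }
        ).sort_index()
        return cls(df, provenance=provenance)

    @property
    def contexts(self) -> pd.Index:
        return self.counts.index

    def __contains__(self, label: str) -> bool:
        return str(label) in self.counts.index

    def p(self, labels: Iterable[str]) -> np.ndarray:
        """Reference singleton proportions for the given context labels."""
        idx = pd.Index(labels)
        missing = idx.difference(self.counts.index)
        if len(missing):
            raise MissingContextError(missing)
        return self.counts["p_ref"].reindex(idx).to_numpy()

    def to_tsv(self, path) -> None:
        """Serialise as TSV plus a JSON provenance sidecar."""
        path = Path(path)
        out = self.counts.reset_index().rename(columns={"index": "context"})
        out.columns = ["context", "n_ref", "s_ref", "p_ref"]
        out.to_csv(path, sep="\t", index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"provenance": self.provenance}, indent=2)
        )

    @classmethod
    def read_tsv(cls, path) -> "ReferenceModel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"context": str})
        counts = df.set_index("context")[["n_ref", "s_ref"]]
        sidecar = path.with_suffix(path.suffix + ".json")
        provenance = ""
        if sidecar.exists():
            provenance = json.loads(sidecar.read_text()).get("provenance", "")
        # p_ref is recomputed from the integer counts, so the round trip
        # is bit-exact regardless of text formatting.
        return cls(counts, provenance=provenance)


@dataclass
class CapsEstimate:
    """CAPS for one variant group, with its binomial confidence interval."""

    group_label: str
    n_variants: int
    observed_singletons: int
    expected_singletons: float
    caps: float
    se: float
    ci_low: float
    ci_high: float
    extra: dict = field(default_factory=dict)

    def ci_overlaps(self, other: "CapsEstimate") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


def _estimate_from_counts(
    n_c: pd.Series,
    s_c: pd.Series,
    model: ReferenceModel,
    label: str = "group",
    ci_method: str = "normal",
    conf: float = 0.95,
) -> CapsEstimate:
    """CAPS from per-context (n, s) counts; the shared core of all paths."""
    p_ref = model.p(n_c.index)
    n = np.asarray(n_c, dtype=float)
    N = int(n.sum())
    if N < 1:
        raise EmptyGroupError(f"group {label!r} is empty")
    S = int(np.asarray(s_c).sum())
    E = float(n @ p_ref)
    caps = (S - E) / N
    p_hat = S / N
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / N))
    z = float(stats.norm.ppf(0.5 + conf / 2.0))
    if p_hat in (0.0, 1.0):
        logger.warning(
            "group %r has p_hat=%g; normal-approximation CI collapses to a point "
            "(consider ci_method='wilson')",
            label,
            p_hat,
        )
    if ci_method == "normal":
        lo, hi = caps - z * se, caps + z * se
    elif ci_method == "wilson":
        denom = 1.0 + z * z / N
        centre = (p_hat + z * z / (2 * N)) / denom
        half = z * np.sqrt(p_hat * (1 - p_hat) / N + z * z / (4 * N * N)) / denom
        lo, hi = centre - half - E / N, centre + half - E / N
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CapsEstimate(
        group_label=label,
        n_variants=N,
        observed_singletons=S,
        expected_singletons=E,
        caps=float(caps),
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def _group_counts(group: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    g = group.groupby("context_label", sort=True)["is_singleton"]
    return g.size(), g.sum()


def compute_caps(
    group: pd.DataFrame,
    model: ReferenceModel,
    label: str = "group",
    ci_method: str = "normal",
    conf: float = 0.95,
) -> CapsEstimate:
    """CAPS of one variant group against a reference model.

    Raises :class:`EmptyGroupError` on an empty group and
    :class:`MissingContextError` when the group contains context classes
    the model has never seen (silently dropping them would bias the
    statistic).
    """
    if len(group) == 0:
        raise EmptyGroupError(f"group {label!r} is empty")
    n_c, s_c = _group_counts(group)
    return _estimate_from_counts(n_c, s_c, model, label=label, ci_method=ci_method, conf=conf)


def compute_maps(
    group: pd.DataFrame,
    model: ReferenceModel,
    mutability: MutabilityTable,
    label: str = "group",
    ci_method: str = "normal",
    conf: float = 0.95,
) -> CapsEstimate:
    """Simplified MAPS: expectation from a singletons-by-mutability fit.

    Reference per-context singleton proportions are regressed on
    log10(mutability) by least squares weighted by the per-context
    reference counts; fitted proportions are clipped to [0, 1] before
    forming the expectation.  When the regression is saturated (as many
    distinct mutability values as parameters) MAPS and CAPS coincide.
    """
    if len(group) == 0:
        raise EmptyGroupError(f"group {label!r} is empty")
    mu = pd.Series(mutability)
    needed = model.contexts.union(pd.Index(group["context_label"].unique()))
    missing = needed.difference(mu.index)
    if len(missing):
        raise MissingContextError(missing, where="mutability table")
    x = np.log10(mu.reindex(model.contexts).to_numpy(dtype=float))
    if len(np.unique(x)) < 2:
        raise DegenerateFitError("mutability is constant across reference contexts")
    y = model.counts["p_ref"].to_numpy(dtype=float)
    w = np.sqrt(model.counts["n_ref"].to_numpy(dtype=float))
    coef = np.polyfit(x, y, 1, w=w)
    n_c, s_c = _group_counts(group)
    x_g = np.log10(mu.reindex(n_c.index).to_numpy(dtype=float))
    p_fit = np.clip(np.polyval(coef, x_g), 0.0, 1.0)
    n = n_c.to_numpy(dtype=float)
    N = int(n.sum())
    S = int(s_c.sum())
    E = float(n @ p_fit)
    # Reuse the CI machinery by substituting the fitted expectation.
    est = _estimate_from_counts(n_c, s_c, model, label=label, ci_method=ci_method, conf=conf)
    shift = (E - est.expected_singletons) / N
    return CapsEstimate(
        group_label=label,
        n_variants=N,
        observed_singletons=S,
        expected_singletons=E,
        caps=est.caps - shift,
        se=est.se,
        ci_low=est.ci_low - shift,
        ci_high=est.ci_high - shift,
    )


GroupKey = Union[str, pd.Series, Callable[[pd.DataFrame], pd.Series]]


def caps_by_group(
    table: pd.DataFrame,
    model: ReferenceModel,
    key: GroupKey,
    ci_method: str = "normal",
    conf: float = 0.95,
) -> list[CapsEstimate]:
    """CAPS for every non-empty group of a partition, sorted by label.

    ``key`` is a column name, a label Series aligned with the table, or
    a callable mapping the table to such a Series.
    """
    if callable(key):
        labels = key(table)
    elif isinstance(key, str):
        labels = table[key]
    else:
        labels = key
    labels = pd.Series(labels, index=table.index)
    estimates = []
    for name, sub in table.groupby(labels.astype(str), sort=True):
        if len(sub) == 0:
            logger.warning("caps_by_group: empty group %r omitted", name)
            continue
        try:
            estimates.append(
                compute_caps(sub, model, label=str(name), ci_method=ci_method, conf=conf)
            )
        except MissingContextError as exc:
            raise MissingContextError(exc.contexts, where=f"model (group {name!r})") from exc
    return estimates


def estimates_to_frame(estimates: Iterable[CapsEstimate]) -> pd.DataFrame:
    """Tabulate estimates with the standard result columns."""
    return pd.DataFrame(
        [
            {
                "group_label": e.group_label,
                "n": e.n_variants,
                "s_obs": e.observed_singletons,
                "s_exp": e.expected_singletons,
                "caps": e.caps,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    )


def write_estimates(estimates: Iterable[CapsEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)


def null_ci_coverage(
    model: ReferenceModel,
    n_groups: int,
    group_size: int,
    rng: np.random.Generator,
    ci_method: str = "normal",
    conf: float = 0.95,
) -> float:
    """Empirical CI coverage under the null, as a percentage.

    Draws ``n_groups`` groups of ``group_size`` variants whose contexts
    follow the reference composition and whose singleton status is
    resampled from the model's own per-context proportions (so the true
    CAPS is zero), and reports 100 x the fraction of groups whose
    interval contains zero.
    """
    weights = model.counts["n_ref"].to_numpy(dtype=float)
    weights = weights / weights.sum()
    p_ref = model.counts["p_ref"].to_numpy(dtype=float)
    idx = model.contexts
    covered = 0
    for _ in range(n_groups):
        n_c = rng.multinomial(group_size, weights)
        s_c = rng.binomial(n_c, p_ref)
        est = _estimate_from_counts(
            pd.Series(n_c, index=idx),
            pd.Series(s_c, index=idx),
            model,
            label="null",
            ci_method=ci_method,
            conf=conf,
        )
        if est.ci_low <= 0.0 <= est.ci_high:
            covered += 1
    return 100.0 * covered / n_groups
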