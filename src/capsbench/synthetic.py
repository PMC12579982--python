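"""Synthetic gnomAD-like cohorts with a designed selection model.

The generator produces variant tables that look like a QC-annotated
exome cohort export — trinucleotide contexts, allele counts, filter
flags, coverage, callable fraction, predictor scores, ClinVar labels —
while every quantity the pipeline estimates has a known design value.

Generative model, per variant:

1. a context class ``c`` is drawn from ``context_freqs``;
2. a selection-mixture component ``k`` (weight ``w_k``, selection
   strength ``s_k`` in [0, 1]) is drawn; ``s = 0`` is neutral;
3. the singleton probability is ``p = p_neutral(c) + s * (1 - p_neutral(c))``
   — selection moves the non-singleton mass toward singletons, so the
   designed CAPS of any (component, context)-definable group has the
   closed form implemented by :func:`expected_caps`;
4. the allele count is 1 with probability ``p``, else ``1 +`` a
   geometric draw (>= 2; the non-singleton tail is cosmetic);
5. each simulated tool scores the variant as an affine map of
   ``clip01(s + Normal(0, noise_sd))`` onto its registered range,
   inverted for lower-is-deleterious tools; a tool may return no score
   below a raw floor (emulating predictors that only score variants
   they deem deleterious);
6. ClinVar labels follow thresholds on ``s`` with star-tier-dependent
   misclassification; QC fields (flags, coverage, callable fraction)
   are drawn independently of everything else.

The reference table is the same model with ``s = 0`` throughout and
synonymous consequence, so it plays the near-neutral reference role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .contexts import ContextLabel, enumerate_context_labels
from .errors import ConfigurationError, UnsupportedPredicateError
from .tools import HIGHER, LOWER, ToolMeta

logger = logging.getLogger(__name__)

#: Default selection mixture: half neutral, a moderate and an extreme tail.
DEFAULT_MIXTURE = ((0.5, 0.0), (0.3, 0.3), (0.2, 0.8))

_SPACE_SEED = 104729  # fixes the default context space, independent of cohort seed


@dataclass(frozen=True)
class ToolSim:
    """A simulated predictor: orientation, noise level, score range.

    ``noise_sd`` is the standard deviation of the Gaussian noise added
    to the latent selection strength before clipping; smaller noise
    means a more faithful predictor.  ``missing_below`` (raw scale)
    makes the tool return no score for variants below that latent
    level, emulating tools that only score putatively deleterious
    variants.
    """

    name: str
    orientation: str = HIGHER
    noise_sd: float = 0.15
    missing_below: Optional[float] = None
    score_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError(f"tool {self.name}: negative noise_sd")
        if self.orientation not in (HIGHER, LOWER):
            raise ConfigurationError(f"tool {self.name}: bad orientation")

    def raw_to_score(self, raw):
        """Map raw [0, 1] deleteriousness onto the tool's score scale."""
        r = np.clip(raw, 0.0, 1.0)
        if self.orientation == LOWER:
            r = 1.0 - r
        lo, hi = self.score_range
        return lo + r * (hi - lo)

    def threshold_for_raw(self, raw: float) -> float:
        """Score-scale threshold equivalent to a raw deleteriousness cutoff."""
        return float(self.raw_to_score(raw))

    def meta(self, threshold: Optional[float] = None, label: str = "") -> ToolMeta:
        return ToolMeta(
            name=self.name,
            orientation=self.orientation,
            valid_range=self.score_range,
            deleterious_label=label,
            default_threshold=threshold,
        )


def default_tools() -> tuple[ToolSim, ...]:
    """Five predictors spanning the fidelity range seen in practice.

    The REVEL- and CADD-like tools are the least noisy; the MutPred-like
    tool scores only variants above a raw floor, so it induces the
    complete-case reduction a real multi-tool comparison faces.
    """
    return (
        ToolSim("REVEL", HIGHER, noise_sd=0.12),
        ToolSim("CADD", HIGHER, noise_sd=0.15, score_range=(0.0, 40.0)),
        ToolSim("SIFT", LOWER, noise_sd=0.20),
        ToolSim("PolyPhen", HIGHER, noise_sd=0.20),
        ToolSim("MutPred", HIGHER, noise_sd=0.25, missing_below=0.25),
    )


@dataclass(frozen=True)
class ClinvarModel:
    """Label model: thresholds on latent deleteriousness + star-tier noise.

    A fraction of study variants receive a ClinVar record.  The true
    class comes from thresholds on ``s`` (benign below, pathogenic
    above, uncertain between); the recorded class is flipped to a
    random other class with a per-star-tier misclassification rate
    (worst at 0 stars).  ``miscalibrated_expert_benign`` makes half of
    the 3-star uncertain-grade variants carry a "benign" label — the
    scenario where expert-panel benign calls are indistinguishable from
    VUSs.
    """

    labelled_fraction: float = 0.15
    benign_max_s: float = 0.05
    pathogenic_min_s: float = 0.5
    star_probs: tuple[float, ...] = (0.45, 0.3, 0.15, 0.1)
    misclass_by_star: tuple[float, ...] = (0.25, 0.15, 0.08, 0.03)
    likely_fraction: float = 0.5
    miscalibrated_expert_benign: bool = False

    def __post_init__(self):
        if abs(sum(self.star_probs) - 1.0) > 1e-9:
            raise ConfigurationError("star_probs must sum to 1")
        if not 0 <= self.labelled_fraction <= 1:
            raise ConfigurationError("labelled_fraction must be in [0, 1]")


@dataclass(frozen=True)
class QCModel:
    """Rates of QC-failing rows, drawn independently of everything else."""

    flag_rate: float = 0.03
    low_coverage_rate: float = 0.05
    low_callable_rate: float = 0.03

    def __post_init__(self):
        for r in (self.flag_rate, self.low_coverage_rate, self.low_callable_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError("QC rates must be in [0, 1]")


def default_context_space(
    seed: int = _SPACE_SEED,
) -> tuple[dict[str, float], dict[str, float]]:
    """Context frequencies (Dirichlet) and neutral singleton proportions.

    Frequencies come from a Dirichlet(5) draw over all 104 classes at a
    fixed seed: class abundances vary severalfold, as exome context
    counts do, but no class is vanishingly rare — every class is
    well-populated in any cohort large enough to build a reference
    model from.  Neutral singleton proportions are drawn uniformly in
    [0.30, 0.60] — the range spanned by exome context classes — with
    methylated CpG C>T classes shifted downward (higher methylation,
    higher recurrent mutation, fewer singletons).
    """
    rng = np.random.default_rng(seed)
    labels = [str(c) for c in enumerate_context_labels(methylation=True)]
    freqs = rng.dirichlet(np.full(len(labels), 5.0))
    p = rng.uniform(0.30, 0.60, len(labels))
    for i, lab in enumerate(labels):
        meth = ContextLabel.parse(lab).methylation
        if meth is not None:
            p[i] = np.clip(p[i] - 0.05 * (meth + 1), 0.20, 0.60)
    return dict(zip(labels, freqs)), dict(zip(labels, p))


_DEFAULT_SPACE: Optional[tuple] = None


def _space():
    global _DEFAULT_SPACE
    if _DEFAULT_SPACE is None:
        _DEFAULT_SPACE = default_context_space()
    return _DEFAULT_SPACE


@dataclass(frozen=True)
class SyntheticParams:
    """Full generative description of a synthetic cohort."""

    n_variants: int = 20_000
    n_reference: int = 100_000
    context_freqs: Mapping[str, float] = field(default_factory=lambda: _space()[0])
    p_neutral: Mapping[str, float] = field(default_factory=lambda: _space()[1])
    mixture: tuple[tuple[float, float], ...] = DEFAULT_MIXTURE
    tools: tuple[ToolSim, ...] = field(default_factory=default_tools)
    clinvar_model: ClinvarModel = field(default_factory=ClinvarModel)
    qc_model: QCModel = field(default_factory=QCModel)
    seed: int = 0

    def __post_init__(self):
        freqs = np.array(list(self.context_freqs.values()), dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ConfigurationError("context_freqs must be a probability vector")
        if set(self.context_freqs) != set(self.p_neutral):
            raise ConfigurationError("context_freqs and p_neutral must share contexts")
        p = np.array(list(self.p_neutral.values()), dtype=float)
        if ((p <= 0) | (p >= 1)).any():
            raise ConfigurationError("p_neutral values must lie in (0, 1)")
        w = np.array([w for w, _ in self.mixture], dtype=float)
        s = np.array([s for _, s in self.mixture], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ConfigurationError("mixture weights must be a probability vector")
        if ((s < 0) | (s > 1)).any():
            raise ConfigurationError("selection strengths must lie in [0, 1]")
        names = [t.name for t in self.tools]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate tool names")

    def tool_registry(self) -> dict[str, ToolMeta]:
        """ToolMeta registry matching the simulated tools."""
        return {t.name: t.meta() for t in self.tools}


def toy_params(**overrides) -> SyntheticParams:
    """A two-context preset small enough for hand-checkable tests."""
    defaults = dict(
        n_variants=200,
        n_reference=1000,
        context_freqs={"ACA>G": 0.5, "CTG>A": 0.5},
        p_neutral={"ACA>G": 0.4, "CTG>A": 0.6},
        tools=(ToolSim("toy", HIGHER, noise_sd=0.1),),
        clinvar_model=ClinvarModel(labelled_fraction=0.5),
    )
    defaults.update(overrides)
    return SyntheticParams(**defaults)


class Cohort(NamedTuple):
    reference: pd.DataFrame
    study: pd.DataFrame
    truth: pd.DataFrame


_FLAG_POOL = np.array(["RF", "AC0", "InbreedingCoeff"], dtype=object)
_AUTOSOMES = [str(i) for i in range(1, 23)]
_CHROMS = np.array(_AUTOSOMES + ["X", "Y"], dtype=object)
_CHROM_P = np.array([0.95 / 22] * 22 + [0.03, 0.02])


def _parse_space(params: SyntheticParams):
    labels = np.array(list(params.context_freqs), dtype=object)
    freqs = np.array([params.context_freqs[l] for l in labels], dtype=float)
    freqs = freqs / freqs.sum()
    pneu = np.array([params.p_neutral[l] for l in labels], dtype=float)
    parsed = [ContextLabel.parse(l) for l in labels]
    return labels, freqs, pneu, parsed


def _make_table(
    rng: np.random.Generator,
    n: int,
    mixture: Sequence[tuple[float, float]],
    params: SyntheticParams,
    consequence: str,
    start_pos: int,
    scored: bool,
    labelled: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    from .contexts import revcomp, complement

    labels, freqs, pneu, parsed = _parse_space(params)
    w = np.array([wk for wk, _ in mixture], dtype=float)
    s_of = np.array([sk for _, sk in mixture], dtype=float)

    ctx_idx = rng.choice(len(labels), size=n, p=freqs)
    comp = rng.choice(len(w), size=n, p=w / w.sum())
    s = s_of[comp]
    p_c = pneu[ctx_idx]
    p_sing = p_c + s * (1.0 - p_c)
    singleton = rng.random(n) < p_sing
    allele_count = np.where(singleton, 1, 1 + rng.geometric(0.3, size=n))

    # Emit half the records on the purine strand so context collapse is
    # exercised on every run.
    flip = rng.random(n) < 0.5
    fwd_ctx = np.array([lab.context for lab in parsed], dtype=object)
    fwd_alt = np.array([lab.alt for lab in parsed], dtype=object)
    rc_ctx = np.array([revcomp(lab.context) for lab in parsed], dtype=object)
    rc_alt = np.array([complement(lab.alt) for lab in parsed], dtype=object)
    lab_meth = np.array(
        [np.nan if lab.methylation is None else lab.methylation for lab in parsed]
    )
    ctx3 = np.where(flip, rc_ctx[ctx_idx], fwd_ctx[ctx_idx])
    alt = np.where(flip, rc_alt[ctx_idx], fwd_alt[ctx_idx])
    ref = np.array([c[1] for c in ctx3], dtype=object)
    meth = lab_meth[ctx_idx]

    qc = params.qc_model
    flagged = rng.random(n) < qc.flag_rate
    flags = np.where(flagged, rng.choice(_FLAG_POOL, size=n), "")
    low_cov = rng.random(n) < qc.low_coverage_rate
    coverage = np.where(low_cov, rng.uniform(5, 30, n), rng.uniform(30, 100, n))
    low_call = rng.random(n) < qc.low_callable_rate
    callable_fraction = np.where(
        low_call, rng.uniform(0.2, 0.8, n), rng.uniform(0.8, 1.0, n)
    )

    df = pd.DataFrame(
        {
            "chrom": rng.choice(_CHROMS, size=n, p=_CHROM_P),
            "pos": np.arange(start_pos, start_pos + n, dtype=np.int64),
            "ref": ref,
            "alt": alt,
            "context3": ctx3,
            "methylation_level": pd.array(meth, dtype="Int64"),
            "allele_count": allele_count.astype(np.int64),
            "is_singleton": singleton,
            "filter_flags": flags,
            "callable_fraction": np.round(callable_fraction, 6),
            "coverage": np.round(coverage, 6),
            "consequence": consequence,
            "context_label": labels[ctx_idx],
        }
    )

    if scored:
        for tool in params.tools:
            raw = np.clip(s + rng.normal(0.0, tool.noise_sd, n), 0.0, 1.0)
            score = tool.raw_to_score(raw)
            if tool.missing_below is not None:
                score = np.where(raw < tool.missing_below, np.nan, score)
            df[f"score_{tool.name}"] = score

    if labelled:
        sig, stars, status = _clinvar_labels(rng, s, params.clinvar_model)
        df["clinvar_significance"] = sig
        df["clinvar_review_status"] = status
        df["clinvar_stars"] = pd.array(
            np.where(stars < 0, np.nan, stars).astype(float), dtype="Int64"
        )

    truth = pd.DataFrame(
        {
            "pos": df["pos"],
            "component": comp,
            "s": s,
            "p_singleton": p_sing,
            "context_label": df["context_label"],
        }
    )
    return df, truth


_STATUS_BY_STAR = {
    3: "reviewed by expert panel",
    2: "criteria provided, multiple submitters, no conflicts",
    1: "criteria provided, single submitter",
    0: "no assertion criteria provided",
}


def _clinvar_labels(rng: np.random.Generator, s: np.ndarray, cm: ClinvarModel):
    n = len(s)
    sig = np.full(n, "absent", dtype=object)
    status = np.full(n, None, dtype=object)
    stars = np.full(n, -1, dtype=np.int64)
    idx = np.flatnonzero(rng.random(n) < cm.labelled_fraction)
    if idx.size == 0:
        return sig, stars, status
    sv = s[idx]
    true_cls = np.where(sv <= cm.benign_max_s, 0, np.where(sv >= cm.pathogenic_min_s, 2, 1))
    st = rng.choice(4, size=idx.size, p=np.asarray(cm.star_probs))
    flip = rng.random(idx.size) < np.asarray(cm.misclass_by_star)[st]
    flipped = (true_cls + 1 + rng.integers(0, 2, idx.size)) % 3
    cls = np.where(flip, flipped, true_cls)
    if cm.miscalibrated_expert_benign:
        expert_vus = (st == 3) & (true_cls == 1) & (rng.random(idx.size) < 0.5)
        cls = np.where(expert_vus, 0, cls)
    names = np.array(["benign", "uncertain", "pathogenic"], dtype=object)[cls]
    likely = rng.random(idx.size) < cm.likely_fraction
    names = np.where((names == "benign") & likely, "likely_benign", names)
    names = np.where((names == "pathogenic") & likely, "likely_pathogenic", names)
    sig[idx] = names
    stars[idx] = st
    status[idx] = np.array([_STATUS_BY_STAR[k] for k in st], dtype=object)
    return sig, stars, status


def generate_cohort(params: SyntheticParams, include_reference: bool = True) -> Cohort:
    """Generate (reference, study, truth) tables from one seed.

    The reference is drawn with ``s = 0`` throughout (synonymous
    consequence); the study carries the selection mixture, tool scores
    and ClinVar labels.  Reference and study use independent spawned
    RNG streams, so the study is bit-identical whether or not the
    reference is generated.
    """
    ref_ss, study_ss = np.random.SeedSequence(params.seed).spawn(2)
    if include_reference:
        reference, _ = _make_table(
            np.random.default_rng(ref_ss),
            params.n_reference,
            ((1.0, 0.0),),
            params,
            consequence="synonymous",
            start_pos=1,
            scored=False,
            labelled=False,
        )
    else:
        reference = pd.DataFrame()
    study, truth = _make_table(
        np.random.default_rng(study_ss),
        params.n_variants,
        params.mixture,
        params,
        consequence="missense",
        start_pos=params.n_reference + 1,
        scored=True,
        labelled=True,
    )
    return Cohort(reference=reference, study=study, truth=truth)


@dataclass(frozen=True)
class GroupSpec:
    """A group definable on the (component, context) marginals.

    ``components`` / ``contexts`` restrict to subsets (None = all).  A
    realized-record ``predicate`` may be attached for Monte-Carlo work
    against the truth table, but closed-form expectations are only
    available for marginal groups.
    """

    components: Optional[tuple[int, ...]] = None
    contexts: Optional[tuple[str, ...]] = None
    predicate: Optional[Callable[[pd.DataFrame], pd.Series]] = None


def expected_caps(params: SyntheticParams, group: Optional[GroupSpec] = None) -> float:
    """The designed CAPS of a marginal group, in closed form.

    For group-conditional component weights w' and context frequencies
    f', the design value is sum_c f'_c sum_k w'_k s_k (1 - p_neutral(c)).
    Because selection acts as p = p_c + s (1 - p_c), this is exactly the
    value the estimator recovers when the reference model equals
    p_neutral.
    """
    group = group or GroupSpec()
    if group.predicate is not None:
        raise UnsupportedPredicateError(
            "closed-form expected CAPS requires a (component, context) marginal group; "
            "use the truth table for realized-noise predicates"
        )
    labels, freqs, pneu, _ = _parse_space(params)
    w = np.array([wk for wk, _ in params.mixture], dtype=float)
    s = np.array([sk for _, sk in params.mixture], dtype=float)
    comp_mask = np.ones(len(w), dtype=bool)
    if group.components is not None:
        comp_mask[:] = False
        comp_mask[list(group.components)] = True
    ctx_mask = np.ones(len(labels), dtype=bool)
    if group.contexts is not None:
        keep = set(group.contexts)
        ctx_mask = np.array([l in keep for l in labels])
    w_sel = w[comp_mask]
    if w_sel.sum() == 0 or freqs[ctx_mask].sum() == 0:
        raise ConfigurationError("group has zero probability mass")
    w_sel = w_sel / w_sel.sum()
    f_sel = freqs[ctx_mask] / freqs[ctx_mask].sum()
    mean_s = float(w_sel @ s[comp_mask])
    return float(f_sel @ (mean_s * (1.0 - pneu[ctx_mask])))


def generate_mutability_table(
    params: SyntheticParams,
    scatter: float = 0.0,
    seed: Optional[int] = None,
    intercept: float = 0.8,
    slope: float = 0.1,
) -> pd.Series:
    """Per-context relative mutation rates consistent with ``p_neutral``.

    Constructed so that ``p_neutral(c) = intercept - slope * log10(mu_c)``
    plus optional Gaussian scatter on the log-rate: with ``scatter=0``
    the neutral singleton proportion is exactly linear in log10
    mutability, which makes the simplified MAPS regression exact.
    """
    labels, _, pneu, _ = _parse_space(params)
    log_mu = (intercept - pneu) / slope
    if scatter > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        log_mu = log_mu + rng.normal(0.0, scatter, len(log_mu))
    return pd.Series(10.0 ** log_mu, index=pd.Index(labels, name="context"), name="mu")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_mutability_table(mu: pd.Series, path) -> None:
    mu.rename("mu").to_csv(path, sep="\t", index=True, header=True)


def read_mutability_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"context": str})
    return df.set_index("context")["mu"]
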