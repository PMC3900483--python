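"""Simulation harness and evaluation metrics.

Runs the rare-blocking tests over streams of simulated replicates and
reports empirical type-I error and power (with critical-value calibration so
methods with different finite-sample size can be compared at equal type-I
error), plus gene-level ROC/AUC summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import family_stats, rb_core
from .blocking import make_partition
from .pedigree_data import GeneRegion
from dataclasses import replace

from .simulator import SimConfig, StudyTemplate, build_template, generate_replicate

__all__ = [
    "NOMINAL_ALPHA",
    "PowerStudyResult",
    "validity_scenarios",
    "run_rb_scenario",
    "empirical_type1_power",
    "calibrate_critical_value",
    "roc_auc",
]

#: nominal significance level of the validity study
NOMINAL_ALPHA = 0.01

#: per-allele log odds ratios of the two effect magnitudes
SMALLER_EFFECT = float(np.log(2.0))
LARGER_EFFECT = float(np.log(4.0))


def validity_scenarios(seed: int, n_pedigrees: int = 1000) -> dict[str, SimConfig]:
    """The validity-study scenario set: one null and four effect settings.

    Three causal SNVs are drawn (with the seeded stream) among the rare but
    polymorphic SNVs (0.005 <= MAF <= 0.05); effects are per-allele log odds
    ratios of ln(2) (smaller) or ln(4) (larger), either all risk
    ("same" direction) or two risk one protective ("mixed").  All scenarios
    share the pedigree set size and the LD design of :class:`SimConfig`'s
    defaults; scenario configs get distinct sub-seeds so replicate streams
    are independent between scenarios.
    """
    base = SimConfig(seed=seed, n_pedigrees=n_pedigrees)
    rng = np.random.default_rng([seed, 202])
    eligible = np.flatnonzero((base.mafs >= 0.005) & (base.mafs <= 0.05))
    causal = tuple(int(c) for c in sorted(rng.choice(eligible, 3, replace=False)))
    b1, b2 = SMALLER_EFFECT, LARGER_EFFECT
    effect_sets = {
        "null": (),
        "smaller_same": (b1, b1, b1),
        "smaller_mixed": (b1, b1, -b1),
        "larger_same": (b2, b2, b2),
        "larger_mixed": (b2, b2, -b2),
    }
    out = {}
    for k, (name, betas) in enumerate(effect_sets.items()):
        cfg = base.with_betas(causal if betas else (), betas)
        out[name] = replace(cfg, seed=int(np.random.default_rng([seed, 303 + k]).integers(2**31)))
    return out


@dataclass
class PowerStudyResult:
    method: str
    scheme: str
    parameter: int | None
    n_replicates: int
    alpha: float
    empirical_type1: float
    type1_se: float
    empirical_power: float
    power_se: float
    calibrated_critical_value: float
    calibrated_power: float


def _partitions_for(region: GeneRegion, specs, genotypes=None, founder_rows=None):
    parts = {}
    for method, scheme, parameter in specs:
        key = (scheme, parameter)
        if key not in parts:
            parts[key] = make_partition(
                region, scheme, parameter, genotypes=genotypes, founder_rows=founder_rows
            )
    return parts


def run_rb_scenario(
    config: SimConfig,
    n_replicates: int,
    specs: list[tuple[str, str, int | None]],
    template: StudyTemplate | None = None,
    first_replicate: int = 0,
    progress=None,
) -> pd.DataFrame:
    """Run rb tests over simulated replicates.

    ``specs`` is a list of ``(method, scheme, parameter)`` with method in
    {"pdt", "fbat"}.  Returns a tidy frame with one row per replicate and
    spec: ``replicate  method  scheme  parameter  B  S  df  p``.  Replicates
    where a gene is entirely uninformative yield NaN statistics.
    """
    if n_replicates <= 0:
        raise ValueError("need at least one replicate")
    if template is None:
        template = build_template(config)
    methods = sorted({m for m, _, _ in specs})
    rows = []
    partitions = None
    for r in range(first_replicate, first_replicate + n_replicates):
        rep = generate_replicate(config, r, template=template)
        if partitions is None:
            # deterministic schemes: geometry only; adaptive uses founder LD
            partitions = _partitions_for(
                rep.region, specs, rep.genotypes, template.founder_rows
            )
        mats = {}
        for method in methods:
            if method == "pdt":
                values, null_vars = family_stats.pdt_matrix(
                    rep.genotypes, rep.affection, template.nuclear
                )
            else:
                values, null_vars = family_stats.fbat_matrix(
                    rep.genotypes, rep.affection, template.nuclear
                )
            informative = (null_vars > 0).any(axis=1) | (values != 0).any(axis=1)
            mats[method] = rb_core.PerPedigreeStatMatrix(
                values, null_vars, informative, method, template.nuclear.family_ids
            )
        for method, scheme, parameter in specs:
            part = partitions[(scheme, parameter)]
            stats = mats[method]
            try:
                x, mu = rb_core.block_aggregate(stats, part)
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    z, _ = rb_core.block_standardize(x, mu, stats.informative)
                s, df, p = rb_core.combine_blocks(z)
            except rb_core.UninformativeGeneError:
                s, df, p = np.nan, 0, np.nan
            rows.append(
                {
                    "replicate": r,
                    "method": method,
                    "scheme": scheme,
                    "parameter": parameter,
                    "B": part.n_blocks,
                    "S": s,
                    "df": df,
                    "p": p,
                }
            )
        if progress is not None:
            progress(r)
    return pd.DataFrame(rows)


def calibrate_critical_value(null_statistics, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of a null statistic sample."""
    stats = np.asarray(null_statistics, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size < 100:
        raise ValueError("need >= 100 null statistics to calibrate")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return float(np.quantile(stats, 1.0 - alpha))


def empirical_type1_power(
    null_config: SimConfig,
    alt_config: SimConfig,
    method: str,
    scheme: str,
    parameter: int | None,
    n_replicates: int,
    alpha: float,
    template: StudyTemplate | None = None,
) -> PowerStudyResult:
    """Empirical type-I error and power of one rb test specification.

    Rejections are counted at nominal ``alpha``; additionally, power is
    recomputed at the critical value calibrated from the null statistic
    sample, which equalizes the type-I error across methods.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if template is None:
        template = build_template(null_config)
    spec = [(method, scheme, parameter)]
    null = run_rb_scenario(null_config, n_replicates, spec, template=template)
    alt = run_rb_scenario(alt_config, n_replicates, spec, template=template)

    t1 = float(np.mean(null["p"].to_numpy() <= alpha))
    pw = float(np.mean(alt["p"].to_numpy() <= alpha))
    crit = calibrate_critical_value(null["S"].to_numpy(), alpha)
    cal_pw = float(np.mean(alt["S"].to_numpy() > crit))
    n = n_replicates
    return PowerStudyResult(
        method=method,
        scheme=scheme,
        parameter=parameter,
        n_replicates=n,
        alpha=alpha,
        empirical_type1=t1,
        type1_se=float(np.sqrt(t1 * (1 - t1) / n)),
        empirical_power=pw,
        power_se=float(np.sqrt(pw * (1 - pw) / n)),
        calibrated_critical_value=crit,
        calibrated_power=cal_pw,
    )


def roc_auc(p_values: np.ndarray, causal_labels) -> tuple[pd.DataFrame, float]:
    """Gene-level ROC curve and AUC.

    ``p_values`` is (n_genes, n_replicates) (a single replicate may be passed
    as a 1-D array); ``causal_labels`` marks causal genes.  At threshold t,
    TPR = (# causal gene hits) / (n_causal * R) and FPR likewise over
    non-causal genes; the curve is swept over all observed p-values and AUC
    computed by the trapezoid rule.
    """
    p = np.atleast_2d(np.asarray(p_values, dtype=float))
    labels = np.asarray(causal_labels, dtype=bool)
    if labels.size != p.shape[0]:
        raise ValueError("one label per gene required")
    if labels.all() or not labels.any():
        raise ValueError("need both causal and non-causal genes")
    thresholds = np.unique(np.concatenate([[0.0], p[np.isfinite(p)].ravel(), [1.0]]))
    causal = p[labels]
    noncausal = p[~labels]
    tpr = np.array([np.nanmean(causal <= t) for t in thresholds])
    fpr = np.array([np.nanmean(noncausal <= t) for t in thresholds])
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc
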