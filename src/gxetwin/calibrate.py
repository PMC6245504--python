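"""Closed-form calibration of the generating model to target observables.

The generator has a handful of free parameters that the reported variance
components do not pin down: the GPS tagging strength, the reporting parent's
effective heritability, the inter-item correlations behind each scale's
reliability, and the aetiological correlations that are not reported
directly.  All of them are solved analytically (path tracing and algebraic
inversions) so the implied observables match the requested targets exactly in
expectation -- no simulation is involved in calibration.

Key identities used:

* GPS-BMI correlation:  r = lambda * kappa * sqrt(h2_bmi), where ``lambda``
  is the correlation of the standardized *true* typed score with the BMI
  additive factor and ``kappa`` is the analytic attenuation of the measured
  score relative to the true score (weight-estimation noise in the discovery
  GWAS, p-value selection, and null SNPs slipping past the threshold).
* parent-child BMI correlation:  r = sqrt(parent_h2) * 0.5 * sqrt(h2_bmi)
  (one transmission path; the reporting parent's additive value correlates
  0.5 with the child's).
* standardized alpha:  alpha = k rbar / (1 + (k-1) rbar), inverted for rbar.
* phenotypic correlation:  r_P = sum over A/C/E of sqrt(V_i V_j) r_X[i,j],
  solved for the unreported r_X entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import TRAITS, GeneratingModel, InvalidConfigurationError

__all__ = [
    "CalibrationTargets",
    "CalibrationError",
    "lambda_from_target",
    "gps_attenuation",
    "inter_item_correlation",
    "likert_attenuation",
    "calibrate_generator",
    "calibrated_model",
]


class CalibrationError(ValueError):
    """A requested target is infeasible; the message names the violated bound."""


@dataclass
class CalibrationTargets:
    """Printed observables the generator is calibrated to reproduce."""

    gps_bmi_r: float = 0.20
    parent_child_bmi_r: float = 0.26
    scale_alphas: dict = field(default_factory=lambda: {
        "restriction": 0.78, "pressure": 0.61})
    # phenotypic correlations among (bmi_sds, restriction, pressure)
    pheno_r_bmi_restriction: float = 0.19
    pheno_r_bmi_pressure: float = -0.24
    pheno_r_restriction_pressure: float = 0.15
    # reported aetiological correlations (entries the fit tables print)
    r_a_bmi_restriction: float = 0.28
    r_a_bmi_pressure: float = -0.48
    r_e_bmi_restriction: float = 0.20
    r_e_bmi_pressure: float = -0.29
    score_p_threshold: float = 0.001


def lambda_from_target(target_r: float, h2_bmi: float) -> float:
    """Pure path inversion: lambda = r / sqrt(h2), ignoring estimation noise."""
    lam = target_r / np.sqrt(h2_bmi)
    if not 0.0 <= lam <= 1.0:
        raise CalibrationError(
            f"implied gps_tag_lambda {lam:.4f} outside [0, 1]")
    return float(lam)


def _upper_moments(mu: float, sigma: float, c: float):
    """E[X 1(X>c)] and E[X^2 1(X>c)] for X ~ N(mu, sigma^2)."""
    a = (c - mu) / sigma
    p = stats.norm.sf(a)
    phi = stats.norm.pdf(a)
    m1 = mu * p + sigma * phi
    m2 = (mu ** 2 + sigma ** 2) * p + sigma * (mu + c) * phi
    return m1, m2, p


def gps_attenuation(n_causal: int, n_snps: int, discovery_n: float,
                    p_threshold: float = 0.001) -> float:
    """Expected correlation of the measured score with the true typed score.

    Works on the standardized-genotype scale where each of the ``n_causal``
    causal SNPs has true effect b = 1/sqrt(n_causal) (so the true score has
    unit variance) and the discovery GWAS estimates it with standard error
    s = 1/sqrt(discovery_n).  SNPs enter the score when their two-sided
    Wald p-value falls below ``p_threshold``; selected null SNPs contribute
    pure noise to the score variance.
    """
    if not np.isfinite(discovery_n):
        return 1.0
    s = 1.0 / np.sqrt(discovery_n)
    b = 1.0 / np.sqrt(n_causal)
    c = stats.norm.isf(p_threshold / 2.0) * s
    # causal SNPs: both selection tails (by symmetry of +/- effects use b > 0)
    m1_hi, m2_hi, _ = _upper_moments(b, s, c)
    # lower tail X < -c via reflection: Y = -X ~ N(-b, s^2), Y > c
    m1_lo_neg, m2_lo, _ = _upper_moments(-b, s, c)
    e_b1 = m1_hi - m1_lo_neg        # E[bhat 1(selected)]
    e_b2 = m2_hi + m2_lo            # E[bhat^2 1(selected)]
    cov = n_causal * b * e_b1       # Cov(score_hat, score_true); Var(true)=1
    var_causal = n_causal * e_b2
    z = stats.norm.isf(p_threshold / 2.0)
    e_z2_sel = 2.0 * (z * stats.norm.pdf(z) + stats.norm.sf(z))
    var_null = (n_snps - n_causal) * s ** 2 * e_z2_sel
    return float(cov / np.sqrt(var_causal + var_null))


def inter_item_correlation(alpha: float, k: int) -> float:
    """Invert standardized alpha = k r / (1 + (k-1) r) for the inter-item r."""
    r = alpha / (k - (k - 1) * alpha)
    if not 0.0 <= r < 1.0:
        raise CalibrationError(
            f"alpha={alpha} with k={k} implies inter-item r={r:.4f} outside [0, 1)")
    return float(r)


def likert_attenuation(levels: int = 5) -> float:
    """Correlation of an equal-probability ``levels``-point discretization of a
    standard normal with the underlying normal (attenuation per item)."""
    probs = np.arange(1, levels) / levels
    cuts = stats.norm.ppf(probs)
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    values = np.arange(1, levels + 1, dtype=float)
    # E[X 1(cat)] = phi(lower) - phi(upper)
    phi = stats.norm.pdf(edges)
    phi[~np.isfinite(edges)] = 0.0
    cov = np.sum(values * (phi[:-1] - phi[1:]))
    var_d = np.sum(values ** 2) / levels - (np.sum(values) / levels) ** 2
    return float(cov / np.sqrt(var_d))


def _solve_rc_entry(r_p, ra, re, acei, acej, pair: str) -> float:
    ai, ci, ei = acei
    aj, cj, ej = acej
    num = r_p - np.sqrt(ai * aj) * ra - np.sqrt(ei * ej) * re
    den = np.sqrt(ci * cj)
    if den < 1e-12:
        raise CalibrationError(f"no shared-environment variance to absorb "
                               f"the {pair} phenotypic correlation")
    rc = num / den
    if not -1.0 <= rc <= 1.0:
        raise CalibrationError(
            f"implied r_C[{pair}] = {rc:.4f} outside [-1, 1]")
    return float(rc)


def calibrate_generator(model: GeneratingModel,
                        targets: CalibrationTargets) -> GeneratingModel:
    """Return a copy of ``model`` whose free parameters hit the targets.

    Solves, in order: the GPS tagging strength (with analytic attenuation for
    the discovery design carried by ``model``), the reporting parent's
    heritability, the r_C entries involving BMI, and a single shared value
    for the unreported restriction-pressure entry of r_A, r_C and r_E.
    The reported r_A / r_E entries are fixed at their target values.
    """
    ace = {t: model.ace_props[t] for t in TRAITS}
    h2_bmi = ace["bmi_sds"][0]

    kappa = gps_attenuation(model.n_causal, model.n_snps, model.discovery_n,
                            targets.score_p_threshold)
    lam = lambda_from_target(targets.gps_bmi_r, h2_bmi) / kappa
    if lam > 1.0:
        raise CalibrationError(
            f"gps_tag_lambda {lam:.4f} > 1 after attenuation correction "
            f"(kappa={kappa:.4f}); increase discovery_n or lower the target")

    sp = targets.parent_child_bmi_r / (0.5 * np.sqrt(h2_bmi))
    if not 0.0 <= sp <= 1.0:
        raise CalibrationError(
            f"parent-child target {targets.parent_child_bmi_r} implies "
            f"sqrt(parent_h2) = {sp:.4f} outside [0, 1]")
    parent_h2 = float(sp ** 2)

    # shared value for the three unreported restriction-pressure entries
    a_r, c_r, e_r = ace["restriction"]
    a_p, c_p, e_p = ace["pressure"]
    denom = (np.sqrt(a_r * a_p) + np.sqrt(c_r * c_p) + np.sqrt(e_r * e_p))
    rho_rp = targets.pheno_r_restriction_pressure / denom
    if not -1.0 <= rho_rp <= 1.0:
        raise CalibrationError(f"implied restriction-pressure correlation "
                               f"{rho_rp:.4f} outside [-1, 1]")

    rc_br = _solve_rc_entry(targets.pheno_r_bmi_restriction,
                            targets.r_a_bmi_restriction,
                            targets.r_e_bmi_restriction,
                            ace["bmi_sds"], ace["restriction"],
                            "bmi_sds,restriction")
    rc_bp = _solve_rc_entry(targets.pheno_r_bmi_pressure,
                            targets.r_a_bmi_pressure,
                            targets.r_e_bmi_pressure,
                            ace["bmi_sds"], ace["pressure"],
                            "bmi_sds,pressure")

    def corr(ab, ac, bc, name):
        m = np.array([[1.0, ab, ac], [ab, 1.0, bc], [ac, bc, 1.0]])
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise CalibrationError(f"calibrated {name} is not positive "
                                   f"semi-definite")
        return m

    r_a = corr(targets.r_a_bmi_restriction, targets.r_a_bmi_pressure,
               rho_rp, "r_a")
    r_c = corr(rc_br, rc_bp, rho_rp, "r_c")
    r_e = corr(targets.r_e_bmi_restriction, targets.r_e_bmi_pressure,
               rho_rp, "r_e")

    try:
        return model.replace(gps_tag_lambda=float(lam), parent_h2=parent_h2,
                             r_a=r_a, r_c=r_c, r_e=r_e,
                             item_loadings=dict(targets.scale_alphas))
    except InvalidConfigurationError as err:  # pragma: no cover
        raise CalibrationError(str(err)) from err


def calibrated_model(seed: int = 0, **overrides) -> GeneratingModel:
    """The default study-condition model, calibrated to the printed targets.

    ``overrides`` are applied before calibration, so changing the discovery
    design (n_snps, discovery_n, ...) re-derives the tagging strength.
    """
    base = GeneratingModel(seed=seed, **overrides)
    return calibrate_generator(base, CalibrationTargets())
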