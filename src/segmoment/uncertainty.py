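"""Propagation of measurement noise into moment uncertainty.

Two routes, kept deliberately independent of each other:

* :func:`monte_carlo` — simulate a full measurement set (two postures,
  six scale readings, one angle record) n times through the actual
  forward model and estimator, and report the empirical mean/SD of the
  recovered moment.  This is the reference: it captures quantization,
  the magnitude bias of |noisy vector|, and tipping.

* :func:`analytic_sd` — first-order (delta-method) propagation through
  the closed form M⁽¹⁾ = M·|ΔCoM| / (2 sin(θ/2)).  Scale noise enters
  through the CoM-weighting sensitivities (P_i − CoM)/M of each state;
  common-mode support-position noise through the change in barycentric
  weights between the states; angle noise through
  ∂M⁽¹⁾/∂θ = −M·|ΔCoM|·cos(θ/2) / (4 sin²(θ/2)).  Valid in the
  small-noise regime; it knows nothing of quantization beyond the usual
  q/sqrt(12) equivalent and carries no magnitude-bias term.

No bias correction is applied to the estimator itself: the upward bias
of the noisy-vector magnitude is quantified by the Monte Carlo report
(``mc_mean`` vs the true moment) rather than subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .errors import TippingError
from .estimator import MeasurementPair, estimate_moment
from .geometry import as_xy, check_angle, chord_gain
from .simulate import NoiseModel, RigidBodyModel, forward_loads, simulate_session, system_com
from .supports import compute_com

#: Monte Carlo replicates per run; keeps the SD's own relative error
#: near 1/sqrt(2 n) ≈ 1.6% at desk-scale runtime.
DEFAULT_N_REPS = 2000

#: Abort threshold on the fraction of replicates that tip the board.
MAX_TIP_FRACTION = 0.01


@dataclass(frozen=True)
class UncertaintyReport:
    """Monte Carlo + analytic uncertainty of a single measurement set."""

    theta_deg: float
    true_moment_kgcm: float
    mc_mean_kgcm: float
    mc_sd_kgcm: float
    mc_relative_sd_pct: float
    analytic_sd_kgcm: float
    n_reps: int
    n_tipped: int
    #: one-factor-at-a-time relative SDs (% of the true moment) per source
    breakdown_pct: Optional[Dict[str, float]] = None


def _mc_moments(
    model: RigidBodyModel,
    theta_deg: float,
    noise: NoiseModel,
    n_reps: int,
    rng: np.random.Generator,
    mass_tol_kg: float,
) -> tuple[np.ndarray, int]:
    """Simulate-estimate n_reps single-angle sets; returns (moments, n_tipped)."""
    moments = []
    tipped = 0
    session = None
    try:
        session = simulate_session(model, [theta_deg], noise=noise, n_repeats=n_reps, rng=rng)
    except TippingError:
        # fall back to per-replicate simulation so one tip does not void the run
        pass
    if session is not None:
        records = session.records
    else:
        records = []
        for _ in range(n_reps):
            try:
                records.extend(
                    simulate_session(model, [theta_deg], noise=noise, n_repeats=1, rng=rng).records
                )
            except TippingError:
                tipped += 1
    for rec in records:
        pair = MeasurementPair(
            state_alpha=compute_com(rec.alpha, label="alpha"),
            state_beta=compute_com(rec.beta, label="beta"),
            theta_deg=rec.theta_recorded_deg,
        )
        moments.append(estimate_moment(pair, mass_tol_kg=mass_tol_kg).moment_kgcm)
    return np.asarray(moments), tipped


def monte_carlo(
    model: RigidBodyModel,
    theta_deg: float,
    noise: NoiseModel,
    n_reps: int = DEFAULT_N_REPS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    breakdown: bool = False,
) -> UncertaintyReport:
    """Empirical uncertainty of one measurement set at angle θ.

    Repeats simulate→estimate ``n_reps`` times and reports the mean, SD,
    and relative SD (percent of the true moment).  With ``breakdown=True``
    three extra one-factor-at-a-time runs attribute the spread to the
    scale, angle, and position sources.  Replicates that tip the board are
    dropped and counted; the run aborts if more than 1% tip.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for a meaningful SD")
    check_angle(theta_deg)
    if rng is None:
        rng = np.random.default_rng(seed)
    # the estimator's mass gate must not clip the sampled scale noise
    mass_tol_kg = max(1.0, 10.0 * noise.scale_sigma_g) * 6.0 / 1000.0
    moments, tipped = _mc_moments(model, theta_deg, noise, n_reps, rng, mass_tol_kg)
    if tipped > MAX_TIP_FRACTION * n_reps:
        raise TippingError(
            f"{tipped}/{n_reps} Monte Carlo replicates tipped the board; "
            "the configuration is too close to the support boundary"
        )
    truth = model.true_moment_kgcm
    mc_sd = float(moments.std(ddof=1))
    breakdown_pct = None
    if breakdown:
        breakdown_pct = {}
        for source in ("scale", "angle", "position", "drift"):
            sub = noise.only(source)
            if all(
                getattr(sub, f) == 0
                for f in ("scale_sigma_g", "scale_quantum_g", "angle_sigma_deg",
                          "position_sigma_cm", "drift_sigma_cm")
            ):
                continue
            m, _ = _mc_moments(model, theta_deg, sub, n_reps, rng, mass_tol_kg)
            breakdown_pct[source] = 100.0 * float(m.std(ddof=1)) / truth
    return UncertaintyReport(
        theta_deg=float(theta_deg),
        true_moment_kgcm=truth,
        mc_mean_kgcm=float(moments.mean()),
        mc_sd_kgcm=mc_sd,
        mc_relative_sd_pct=100.0 * mc_sd / truth,
        analytic_sd_kgcm=analytic_sd(model, theta_deg, noise),
        n_reps=int(moments.size),
        n_tipped=tipped,
        breakdown_pct=breakdown_pct,
    )


def analytic_sd(model: RigidBodyModel, theta_deg: float, noise: NoiseModel) -> float:
    """First-order SD of the estimated moment for one measurement set, kg·cm.

    Combines, in quadrature: scale noise (plus the q/sqrt(12) quantization
    equivalent) propagated through both states' CoM weights and projected
    on the ΔCoM direction; common-mode support-position noise through the
    difference of the two states' barycentric weights; posture drift as
    equivalent per-reading load noise; and the recorded-angle term.
    Raises :class:`SingularAngleError` at the singular angles.
    """
    gain = chord_gain(theta_deg)  # validates theta
    tri = model.support_triangle
    total = model.total_mass_kg
    state_a = system_com(model, 0.0)
    state_b = system_com(model, theta_deg)
    com_a, com_b = as_xy(state_a.com), as_xy(state_b.com)
    delta = com_a - com_b
    dnorm = float(np.linalg.norm(delta))
    if dnorm == 0.0:
        # segment CoM on the rotation axis: only the (zero-lever) angle term
        return 0.0
    u = delta / dnorm

    # scale noise (+ quantization) through CoM = sum(P_i m_i)/M: dCoM/dm_i = (P_i - CoM)/M
    sigma_m_kg = math.hypot(noise.scale_sigma_g, noise.scale_quantum_g / math.sqrt(12.0)) / 1000.0
    var_dnorm = 0.0
    for com in (com_a, com_b):
        d = tri - com  # (3, 2)
        cov = (sigma_m_kg / total) ** 2 * (d.T @ d)
        var_dnorm += float(u @ cov @ u)

    # common-mode position noise: delta_err = sum_i e_i (w_i^a - w_i^b), e_i iso
    if noise.position_sigma_cm > 0:
        w_a = forward_loads(com_a, 1.0, tri).readings_kg
        w_b = forward_loads(com_b, 1.0, tri).readings_kg
        var_dnorm += noise.position_sigma_cm**2 * float(np.sum((w_a - w_b) ** 2))

    # posture drift -> equivalent load noise per reading: dm_i = M * grad(w_i) . dc
    if noise.drift_sigma_cm > 0:
        a = np.vstack([np.ones(3), tri.T])
        grads = np.linalg.inv(a)[:, 1:]  # (3, 2) rows: dw_i/d(cx, cy)
        for com in (com_a, com_b):
            d = tri - com
            sig2 = (noise.drift_sigma_cm**2) * np.sum(grads**2, axis=1)  # per-reading var of w_i
            cov = d.T @ (d * sig2[:, None])  # masses cancel: (M sig_w / M)^2
            var_dnorm += float(u @ cov @ u)

    sd_from_com = total * math.sqrt(var_dnorm) / gain

    # angle record: dM1/dtheta = -M |Delta| cos(theta/2) / (4 sin^2(theta/2))
    half = math.radians(theta_deg) / 2.0
    sd_from_theta = (
        total
        * dnorm
        * abs(math.cos(half))
        / (4.0 * math.sin(half) ** 2)
        * math.radians(noise.angle_sigma_deg)
    )
    return math.hypot(sd_from_com, sd_from_theta)
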