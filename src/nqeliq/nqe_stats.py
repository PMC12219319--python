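"""Nuclear-quantum-effect and isotope-effect statistics.

The magnitude of an NQE on a property λ is the relative quantum–classical
difference

    Δ_λ = (λ^PI − λ^cl)/λ^PI            (internally a fraction; formatted as %)

and the equilibrium isotope effect under deuteration is

    Δ_λ^{D→H} = (λ^PI,H − λ^PI,D)/λ^PI,D ,

both computed with first-order (delta-method) SEM propagation.  Two derived
quantities: the density relation Δ_ρ = −Δ_vm/(1−Δ_vm) (density trends are
opposite and similar in magnitude to molar volume), and the reduced
temperature T_vm = Δ_vm/α_P^cl — to leading order the temperature shift a
classical liquid needs for its molar volume to match the quantum one.

Note: some texts quote the isotope effect with the opposite sign, as
1 − λ^H/λ^D; this module follows the (λ^H − λ^D)/λ^D convention throughout
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero."""


@dataclass(frozen=True)
class PropertyTriplet:
    """One molecule × one property across the three treatments."""

    tag: str
    classical: float
    pi: float
    pi_deuterated: float
    sem_classical: float = 0.0
    sem_pi: float = 0.0
    sem_pi_deuterated: float = 0.0


@dataclass(frozen=True)
class NQEResult:
    delta: float            # fraction
    delta_sem: float
    isotope_delta: float    # fraction
    isotope_delta_sem: float
    T_vm: float | None = None  # K; only for v_m with α_P^cl available


def _ratio_delta(num_hi: float, denom: float, sem_hi: float, sem_denom: float):
    """(hi − denom)/denom with delta-method SEM."""
    if denom == 0:
        raise UndefinedRatioError("denominator property value is zero")
    val = (num_hi - denom) / denom
    # d/dhi = 1/denom ; d/ddenom = −hi/denom²
    sem = np.hypot(sem_hi / denom, num_hi * sem_denom / denom**2)
    return float(val), float(sem)


def nqe_magnitude(
    lam_pi: float, lam_cl: float, sem_pi: float = 0.0, sem_cl: float = 0.0
) -> tuple[float, float]:
    """Δ_λ = (λ^PI − λ^cl)/λ^PI as a fraction, with propagated SEM."""
    if lam_pi == 0:
        raise UndefinedRatioError("λ^PI is zero")
    val = (lam_pi - lam_cl) / lam_pi
    # d/dλ_pi = λ_cl/λ_pi² ; d/dλ_cl = −1/λ_pi
    sem = np.hypot(lam_cl * sem_pi / lam_pi**2, sem_cl / lam_pi)
    return float(val), float(sem)


def isotope_effect(
    lam_pi_h: float, lam_pi_d: float, sem_h: float = 0.0, sem_d: float = 0.0
) -> tuple[float, float]:
    """Δ_λ^{D→H} = (λ^PI,H − λ^PI,D)/λ^PI,D as a fraction, with SEM."""
    return _ratio_delta(lam_pi_h, lam_pi_d, sem_h, sem_d)


def density_relation(delta_vm: float) -> float:
    """Δ_ρ = −Δ_vm/(1−Δ_vm): the exact NQE on density implied by Δ_vm."""
    if delta_vm >= 1:
        raise ValueError("Δ_vm must be < 1 (fraction)")
    return -delta_vm / (1.0 - delta_vm)


def reduced_temperature(delta_vm: float, alpha_p_cl: float) -> float:
    """T_vm = Δ_vm/α_P^cl (K): first-order classical-to-quantum T shift."""
    if alpha_p_cl <= 0:
        raise ValueError(
            "negative or zero classical expansivity is outside the model scope"
        )
    return delta_vm / alpha_p_cl


def analyze_triplet(triplet: PropertyTriplet, alpha_p_cl: float | None = None) -> NQEResult:
    d, ds = nqe_magnitude(
        triplet.pi, triplet.classical, triplet.sem_pi, triplet.sem_classical
    )
    di, dis = isotope_effect(
        triplet.pi, triplet.pi_deuterated, triplet.sem_pi, triplet.sem_pi_deuterated
    )
    tvm = None
    if triplet.tag == "v_m" and alpha_p_cl is not None:
        tvm = reduced_temperature(d, alpha_p_cl)
    return NQEResult(d, ds, di, dis, tvm)


def replicate_stats(values) -> tuple[float, float]:
    """Mean and SEM = s/√n over independent replicas (n ≥ 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM undefined for fewer than two replicas")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def paired_one_tailed_ttest(errors_a, errors_b) -> tuple[float, float]:
    """Paired one-tailed t-test for H₁: mean(errors_a − errors_b) < 0.

    Typical use: errors_a = |simulation A − experiment| per molecule,
    errors_b likewise for method B; a small p supports A being
    systematically closer to the reference.  Returns (t, p); t follows a
    Student t with n−1 degrees of freedom under H₀.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: degenerate test")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(_scipy_stats.t.cdf(t, df=n - 1))  # one-tailed, lower
    return float(t), p
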