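"""The combined population/family association statistic and its components.

The test addresses mixed study designs in which the same affected
offspring enter both a population-based case-control comparison and a
family-based transmission comparison:

* ``P`` — a trend test on allele counts: the difference between mean case
  and control allele counts, standardized by its null standard error,
  ``P = (R̄ − S̄) / sqrt(σ²(1/N + 1/M))`` with ``σ² = 2p(1−p)`` under
  Hardy–Weinberg equilibrium (or a method-of-moments genotype variance).
* ``F`` — a Wald test of Mendelian segregation, equivalent to the TDT:
  with ``H`` heterozygous parents transmitting ``ΣT_i`` copies of the "1"
  allele, ``F = (ΣT_i − H/2) / sqrt(H/4)``, so that ``F²`` is the classic
  TDT chi-square ``(b − c)²/(b + c)``.
* the combined statistic ``z = [wP + (1−w)F] / sqrt(w² + (1−w)² +
  2w(1−w)τ)``, standard normal under the null, where ``τ`` is the null
  covariance of P and F induced by the shared cases.

Because cases appear in both components, P and F are positively
correlated under the null. Conditional on parental genotypes each case
genotype decomposes into the deterministic contribution of homozygous
parents plus the Bernoulli(½) transmissions from heterozygous parents, so
``Cov(ΣR_j, ΣT_i) = H/4`` and, after standardization,
``τ = sqrt(H) / (2N · sqrt(σ²(1/N + 1/M)))``.

All functions are deterministic; simulation lives in
:mod:`popfam.simulate`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .types import MendelianError, MixedDataset, TestResult

__all__ = [
    "count_transmissions",
    "sigma2_hwe",
    "sigma2_mom",
    "estimate_maf",
    "trend_stat",
    "wald_stat",
    "compute_weight",
    "compute_tau",
    "popfam_stat",
    "popfam_test",
    "popfam_test_batch",
]

#: Sample used to estimate the marker allele frequency entering the null
#: variance sigma^2. "untransmitted" (default) pools the controls with
#: the parental alleles NOT transmitted to the affected offspring — both
#: are unbiased draws from the population even under case ascertainment,
#: unlike the cases themselves. "controls" uses the controls alone;
#: "pooled" uses cases and controls together. All agree in expectation
#: under the null; under an alternative the ascertained cases inflate the
#: pooled estimate.
MAF_SOURCES = ("untransmitted", "controls", "pooled")
VARIANCE_MODES = ("hwe", "mom")
WEIGHT_MODES = ("half", "sample_size")


def count_transmissions(father_g: int, mother_g: int, child_g: int) -> tuple[int, int]:
    """Count informative transmissions in a case-parent trio.

    Returns ``(h, t)`` where ``h`` is the number of heterozygous parents
    and ``t`` the number of "1" alleles the child received from them.
    Homozygous parents transmit deterministically, so ``t`` follows from
    the three unphased genotypes alone.

    Raises
    ------
    MendelianError
        If the genotypes are incompatible with Mendelian transmission.
    """
    for g, who in ((father_g, "father"), (mother_g, "mother"), (child_g, "child")):
        if g not in (0, 1, 2):
            raise ValueError(f"{who} genotype must be in {{0, 1, 2}}, got {g}")
    h = (father_g == 1) + (mother_g == 1)
    t = child_g - ((father_g == 2) + (mother_g == 2))
    if not 0 <= t <= h:
        raise MendelianError(
            f"trio ({father_g}, {mother_g}, {child_g}) is Mendelian-inconsistent"
        )
    return int(h), int(t)


def sigma2_hwe(maf_hat: float) -> float:
    """Allele-count variance ``2p(1−p)`` under Hardy–Weinberg equilibrium."""
    if not 0.0 <= maf_hat <= 1.0:
        raise ValueError(f"maf_hat must be in [0, 1], got {maf_hat}")
    return 2.0 * maf_hat * (1.0 - maf_hat)


def sigma2_mom(g1: int, g2: int, n_total: int) -> float:
    """Method-of-moments allele-count variance, robust to HWE failure.

    ``g1`` and ``g2`` count individuals carrying 1 and 2 copies of the "1"
    allele among ``n_total`` people; the estimator
    ``[4g2 + g1 − n_total·ḡ²]/n_total`` with ``ḡ = (2g2 + g1)/n_total`` is
    the (divide-by-n) sample variance of the individual allele counts.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if g1 < 0 or g2 < 0 or g1 + g2 > n_total:
        raise ValueError("need g1, g2 >= 0 and g1 + g2 <= n_total")
    gbar = (2.0 * g2 + g1) / n_total
    return (4.0 * g2 + g1 - n_total * gbar * gbar) / n_total


def estimate_maf(
    case_g: np.ndarray, control_g: np.ndarray, maf_source: str = "controls"
) -> float:
    """Estimate the marker "1"-allele frequency for the null variance."""
    case_g = np.asarray(case_g)
    control_g = np.asarray(control_g)
    if maf_source == "controls":
        if control_g.size == 0:
            raise ValueError("no controls available to estimate the MAF")
        return float(control_g.sum()) / (2.0 * control_g.size)
    if maf_source == "pooled":
        n = case_g.size + control_g.size
        if n == 0:
            raise ValueError("empty sample")
        return float(case_g.sum() + control_g.sum()) / (2.0 * n)
    raise ValueError(f"unknown maf_source {maf_source!r}")


def trend_stat(
    case_g: Sequence[int] | np.ndarray,
    control_g: Sequence[int] | np.ndarray,
    variance_mode: str = "hwe",
    maf_source: str = "controls",
    maf_hat: float | None = None,
) -> tuple[float, float, float]:
    """Population-based trend statistic on allele counts.

    ``P = (R̄ − S̄) / sqrt(σ²(1/N + 1/M))``, asymptotically N(0,1) under
    no association. With ``variance_mode="hwe"``, ``σ² = 2p̂(1−p̂)`` with
    the allele frequency estimated from ``maf_source`` (or supplied
    directly via ``maf_hat``, e.g. the untransmitted-augmented estimate
    that :func:`popfam_test` computes from trio founders); with
    ``"mom"``, σ² is the method-of-moments genotype variance of the same
    sample.

    Returns
    -------
    (P_stat, sigma2, maf_hat)

    Raises
    ------
    ValueError
        If either sample is empty or the marker is monomorphic in the
        variance-estimation sample (σ² = 0).
    """
    case_g = np.asarray(case_g, dtype=np.int64)
    control_g = np.asarray(control_g, dtype=np.int64)
    N, M = case_g.size, control_g.size
    if N < 1 or M < 1:
        raise ValueError("need at least one case and one control")
    if maf_hat is None:
        maf_hat = estimate_maf(case_g, control_g, maf_source)
    if variance_mode == "hwe":
        sigma2 = sigma2_hwe(maf_hat)
    elif variance_mode == "mom":
        if maf_source == "pooled":
            g = np.concatenate([case_g, control_g])
        else:
            # untransmitted alleles do not form genotypes, so the
            # moment estimator falls back to the control genotypes
            g = control_g
        sigma2 = sigma2_mom(int((g == 1).sum()), int((g == 2).sum()), g.size)
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if sigma2 <= 0.0:
        raise ValueError("marker is monomorphic in the variance sample (sigma2 = 0)")
    P = (case_g.mean() - control_g.mean()) / math.sqrt(sigma2 * (1.0 / N + 1.0 / M))
    return float(P), float(sigma2), float(maf_hat)


def wald_stat(H: int, T_sum: int, p0: float = 0.5) -> float:
    """Family-based Wald statistic of Mendelian segregation.

    Tests whether the transmission rate from heterozygous parents equals
    ``p0`` (½ under Mendel's law): ``F = (ΣT − H·p0)/sqrt(H·p0(1−p0))``.
    At ``p0 = ½`` this is ``2·sqrt(H)·(ΣT/H − ½)`` and ``F²`` equals the
    TDT chi-square ``(b − c)²/(b + c)`` with ``b = ΣT``, ``c = H − ΣT``.
    """
    if H < 1:
        raise ValueError("H must be >= 1 (no informative transmissions)")
    if not 0 <= T_sum <= H:
        raise ValueError("need 0 <= T_sum <= H")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    return float((T_sum - H * p0) / math.sqrt(H * p0 * (1.0 - p0)))


def compute_weight(N: int, M: int, H: int) -> float:
    """Sample-size-based weight ``w = A/(A + H)``.

    ``A = NM/(N + M)`` is half the harmonic mean of the case and control
    counts — the effective per-group size of the population component —
    while ``H`` measures the information available to the family
    component. ``w`` is 1 when there is no family information and decays
    toward 0 as heterozygous parents accumulate.
    """
    if N < 1 or M < 1:
        raise ValueError("need N >= 1 and M >= 1")
    if H < 0:
        raise ValueError("H must be >= 0")
    A = N * M / (N + M)
    return float(A / (A + H))


def compute_tau(N: int, M: int, H: int, sigma2: float) -> float:
    """Null covariance of the standardized trend and Wald statistics.

    Under the null, conditional on the parental genotypes, each case
    genotype is (homozygous-parent contribution) + (Bernoulli(½)
    transmissions from heterozygous parents), and the latter are exactly
    the transmissions counted by the Wald statistic. Hence
    ``Cov(ΣR_j, ΣT_i) = H/4`` and

        τ = sqrt(H) / (2N · sqrt(σ²(1/N + 1/M))).

    The controls are independent of the trios and contribute nothing.
    """
    if N < 1 or M < 1:
        raise ValueError("need N >= 1 and M >= 1")
    if H < 1:
        raise ValueError("H must be >= 1")
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be > 0")
    tau = math.sqrt(H) / (2.0 * N * math.sqrt(sigma2 * (1.0 / N + 1.0 / M)))
    # The plug-in estimate (observed H with estimated sigma^2) can slightly
    # exceed 1 for small samples with rare alleles; a covariance of two
    # unit-variance statistics cannot, so clip.
    return float(min(tau, 1.0))


def popfam_stat(P_stat: float, F_stat: float, w: float, tau: float) -> float:
    """Combine standardized components into one standard-normal statistic.

    ``z = [wP + (1−w)F] / sqrt(w² + (1−w)² + 2w(1−w)τ)`` with
    Var(P) = Var(F) = 1; the denominator is the null standard deviation of
    the numerator given the component covariance τ.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    denom2 = w * w + (1.0 - w) ** 2 + 2.0 * w * (1.0 - w) * tau
    if denom2 <= 0.0:
        raise ValueError("degenerate combination: null variance <= 0")
    return float((w * P_stat + (1.0 - w) * F_stat) / math.sqrt(denom2))


def dataset_maf(dataset: MixedDataset, maf_source: str = "untransmitted") -> float:
    """Population allele-frequency estimate from a mixed dataset.

    ``"untransmitted"`` pools the control alleles with the parental
    alleles not transmitted to the affected offspring (per trio,
    ``father_g + mother_g − child_g``); both subsamples estimate the
    population frequency without ascertainment bias, so the estimate
    stays valid under an alternative.
    """
    if maf_source in ("controls", "pooled"):
        return estimate_maf(dataset.case_g, dataset.control_g, maf_source)
    if maf_source != "untransmitted":
        raise ValueError(f"unknown maf_source {maf_source!r}")
    n_founder_alleles = 2 * dataset.n_trios
    untransmitted = int(
        dataset.father_g.sum() + dataset.mother_g.sum() - dataset.child_g.sum()
    )
    total = 2 * dataset.n_controls + n_founder_alleles
    if total == 0:
        raise ValueError("empty sample")
    return (untransmitted + int(dataset.control_g.sum())) / total


def popfam_test(
    dataset: MixedDataset,
    variance_mode: str = "hwe",
    weight_mode: str = "half",
    p0: float = 0.5,
    maf_source: str = "untransmitted",
) -> TestResult:
    """Run the combined test on a mixed trio/control dataset.

    Parameters
    ----------
    dataset:
        Trios plus controls at one biallelic marker.
    variance_mode:
        ``"hwe"`` (σ² = 2p̂(1−p̂)) or ``"mom"`` (method of moments).
    weight_mode:
        ``"half"`` fixes w = ½ (appropriate when the two components have
        comparable power, e.g. N ≈ M); ``"sample_size"`` uses
        :func:`compute_weight` with the observed H.
    p0:
        Null transmission probability for the Wald component.
    maf_source:
        Sample used to estimate the allele frequency in σ²; see
        :data:`MAF_SOURCES`.

    Notes
    -----
    If no parent is heterozygous (H = 0) the family component carries no
    information and the trend statistic is returned alone (w = 1, τ = 0,
    F reported as 0). The two-sided p-value is ``2(1 − Φ(|z|))``.
    """
    N, M = dataset.n_cases, dataset.n_controls
    if N < 1 or M < 1:
        raise ValueError("dataset must contain at least one case and one control")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    p_hat = dataset_maf(dataset, maf_source)
    try:
        P, sigma2, maf_hat = trend_stat(
            dataset.case_g, dataset.control_g, variance_mode, maf_source,
            maf_hat=p_hat,
        )
    except ValueError:
        if maf_source == "pooled":
            raise
        # the population sample happens to be monomorphic: fall back to
        # the pooled cases + controls for the variance estimate
        P, sigma2, maf_hat = trend_stat(
            dataset.case_g, dataset.control_g, variance_mode, "pooled"
        )
    H, X, T_sum = dataset.H, dataset.X, dataset.T_sum
    if H == 0:
        F, tau, w = 0.0, 0.0, 1.0
        z = P
    else:
        F = wald_stat(H, T_sum, p0)
        tau = compute_tau(N, M, H, sigma2)
        w = 0.5 if weight_mode == "half" else compute_weight(N, M, H)
        z = popfam_stat(P, F, w, tau)
    p_value = float(2.0 * norm.sf(abs(z)))
    return TestResult(
        P_stat=P,
        F_stat=F,
        w=w,
        tau=tau,
        z=z,
        p_value=p_value,
        N=N,
        M=M,
        H=H,
        X=X,
        variance_mode=variance_mode,
        sigma2=sigma2,
        maf_hat=maf_hat,
    )

def popfam_test_batch(
    father_g: np.ndarray,
    mother_g: np.ndarray,
    child_g: np.ndarray,
    control_g: np.ndarray,
    variance_mode: str = "hwe",
    weight_mode: str = "half",
    maf_source: str = "untransmitted",
) -> dict[str, np.ndarray]:
    """Vectorized combined test over many replicates at once.

    The trio genotype arrays have shape ``(n_reps, N)`` and the control
    array ``(n_reps, M)``; each row is one replicate dataset. Returns a
    dict of per-replicate arrays ``P``, ``F``, ``z``, ``tau``, ``w``,
    ``H``, ``T``, ``sigma2`` computed with the same conventions as
    :func:`popfam_test` (rows with H = 0 fall back to the trend
    statistic with w = 1, τ = 0). Intended for Monte-Carlo calibration
    studies where calling :func:`popfam_test` per replicate would
    dominate the runtime.
    """
    father_g = np.asarray(father_g)
    mother_g = np.asarray(mother_g)
    child_g = np.asarray(child_g)
    control_g = np.asarray(control_g)
    if father_g.ndim != 2 or control_g.ndim != 2:
        raise ValueError("expected 2-D (n_reps, sample) genotype arrays")
    n_reps, N = child_g.shape
    M = control_g.shape[1]
    h = (father_g == 1).astype(np.int32) + (mother_g == 1)
    t = child_g.astype(np.int32) - ((father_g == 2).astype(np.int32) + (mother_g == 2))
    if ((t < 0) | (t > h)).any():
        raise MendelianError("batch contains a Mendelian-inconsistent trio")
    H = h.sum(axis=1)
    T = t.sum(axis=1)
    case_sum = child_g.sum(axis=1, dtype=np.int64)
    ctrl_sum = control_g.sum(axis=1, dtype=np.int64)
    if maf_source == "controls":
        maf_hat = ctrl_sum / (2.0 * M)
        var_sample = control_g
    elif maf_source == "pooled":
        maf_hat = (case_sum + ctrl_sum) / (2.0 * (N + M))
        var_sample = None
    elif maf_source == "untransmitted":
        unt = (
            father_g.sum(axis=1, dtype=np.int64)
            + mother_g.sum(axis=1, dtype=np.int64)
            - case_sum
        )
        maf_hat = (unt + ctrl_sum) / (2.0 * (N + M))
        var_sample = control_g
    else:
        raise ValueError(f"unknown maf_source {maf_source!r}")
    if variance_mode == "hwe":
        sigma2 = 2.0 * maf_hat * (1.0 - maf_hat)
    elif variance_mode == "mom":
        if var_sample is None:
            g1 = (child_g == 1).sum(axis=1) + (control_g == 1).sum(axis=1)
            g2 = (child_g == 2).sum(axis=1) + (control_g == 2).sum(axis=1)
            n_tot = N + M
        else:
            g1 = (var_sample == 1).sum(axis=1)
            g2 = (var_sample == 2).sum(axis=1)
            n_tot = M
        gbar = (2.0 * g2 + g1) / n_tot
        sigma2 = (4.0 * g2 + g1 - n_tot * gbar * gbar) / n_tot
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if (sigma2 <= 0).any():
        raise ValueError("monomorphic variance sample in at least one replicate")
    inv_nm = 1.0 / N + 1.0 / M
    P = (case_sum / N - ctrl_sum / M) / np.sqrt(sigma2 * inv_nm)
    informative = H >= 1
    F = np.zeros(n_reps)
    tau = np.zeros(n_reps)
    w = np.ones(n_reps)
    Hs = H[informative].astype(float)
    F[informative] = (T[informative] - Hs / 2.0) / np.sqrt(Hs / 4.0)
    tau[informative] = np.minimum(
        np.sqrt(Hs) / (2.0 * N * np.sqrt(sigma2[informative] * inv_nm)), 1.0
    )
    if weight_mode == "half":
        w[informative] = 0.5
    elif weight_mode == "sample_size":
        A = N * M / (N + M)
        w[informative] = A / (A + Hs)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    z = (w * P + (1.0 - w) * F) / np.sqrt(
        w**2 + (1.0 - w) ** 2 + 2.0 * w * (1.0 - w) * tau
    )
    return {
        "P": P, "F": F, "z": z, "tau": tau, "w": w,
        "H": H, "T": T, "sigma2": sigma2, "maf_hat": np.asarray(maf_hat, dtype=float),
    }
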