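"""Conditional genotype simulation for mixed trio/case-control designs.

The generative model has two biallelic loci: a disease locus with risk
allele frequency ``daf`` and penetrances ``(f0, f1, f2)`` for 0, 1, 2
copies of the risk allele, and a marker SNP in linkage disequilibrium
``D'`` with it. Haplotypes are drawn under random mating; a case-parent
trio is formed by drawing two haplotypes per parent and transmitting one
per parent at random, and the trio is ascertained (rejection-sampled) on
the offspring being affected. Controls are either drawn from the general
population or rejection-sampled on being unaffected. Only the marker
genotypes are returned — the disease locus is latent, as in a real
association study.

The default study conditions are the six penetrance scenarios in
:data:`SCENARIOS` (risk-allele frequency 0.03–0.30, population prevalence
5% with a 4.5% phenocopy rate, marker MAF equal to the DAF, D' = 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .types import MixedDataset, TrioRecord

__all__ = [
    "GeneticModel",
    "HaplotypeFreqs",
    "SCENARIOS",
    "haplotype_freqs",
    "prevalence",
    "simulate_trio",
    "simulate_trios",
    "simulate_control",
    "simulate_controls",
    "simulate_null_dataset",
    "simulate_null_batch",
    "simulate_alt_dataset",
]

#: Marker allele carried by haplotypes 0, 1, 2, 3 (coded (marker, disease)).
_MARKER = np.array([1, 1, 0, 0], dtype=np.int8)
#: Disease allele carried by haplotypes 0, 1, 2, 3.
_DISEASE = np.array([1, 0, 1, 0], dtype=np.int8)

#: Safety cap on rejection-sampling attempts per accepted individual.
MAX_REJECTION_ATTEMPTS = 1_000_000

ControlMode = Literal["population", "unaffected"]


@dataclass(frozen=True)
class GeneticModel:
    """A two-locus disease/marker model.

    Parameters
    ----------
    daf:
        Disease (risk) allele frequency.
    f1, f2:
        Penetrances of the risk-allele heterozygote and homozygote.
    f0:
        Penetrance of the wildtype homozygote (the phenocopy rate).
    marker_maf:
        Marker "1"-allele frequency; defaults to ``daf``.
    dprime:
        Normalized linkage disequilibrium between marker and disease
        locus, with the "1" allele coupled to the risk allele.
    """

    daf: float
    f1: float
    f2: float
    f0: float = 0.045
    marker_maf: float | None = None
    dprime: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.daf < 1.0:
            raise ValueError("daf must be in (0, 1)")
        for name in ("f0", "f1", "f2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.marker_maf is not None and not 0.0 < self.marker_maf < 1.0:
            raise ValueError("marker_maf must be in (0, 1)")
        if not 0.0 <= self.dprime <= 1.0:
            raise ValueError("dprime must be in [0, 1]")

    @property
    def maf(self) -> float:
        """Effective marker allele frequency (defaults to the DAF)."""
        return self.daf if self.marker_maf is None else self.marker_maf

    @property
    def penetrances(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2])

    def null(self) -> "GeneticModel":
        """The matched no-association model (all penetrances equal)."""
        return replace(self, f1=self.f0, f2=self.f0)


#: The six alternative scenarios of the simulation study. Penetrances are
#: tuned so each implies a population prevalence of 5% with phenocopy
#: rate 0.045; none is additive, dominant, multiplicative or recessive.
SCENARIOS: dict[str, GeneticModel] = {
    "S1": GeneticModel(daf=0.03, f1=0.125, f2=0.440),
    "S2": GeneticModel(daf=0.06, f1=0.084, f2=0.218),
    "S3": GeneticModel(daf=0.09, f1=0.066, f2=0.237),
    "S4": GeneticModel(daf=0.12, f1=0.060, f2=0.173),
    "S5": GeneticModel(daf=0.20, f1=0.053, f2=0.100),
    "S6": GeneticModel(daf=0.30, f1=0.050, f2=0.080),
}


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four (marker, disease) haplotypes."""

    q11: float
    q10: float
    q01: float
    q00: float

    def as_probs(self) -> np.ndarray:
        """Probabilities in haplotype order (1,1), (1,0), (0,1), (0,0)."""
        return np.array([self.q11, self.q10, self.q01, self.q00])

    @property
    def marker_maf(self) -> float:
        return self.q11 + self.q10

    @property
    def daf(self) -> float:
        return self.q11 + self.q01

    @property
    def dprime(self) -> float:
        pm, pd = self.marker_maf, self.daf
        d = self.q11 - pm * pd
        if d >= 0:
            dmax = min(pm * (1 - pd), (1 - pm) * pd)
        else:
            dmax = min(pm * pd, (1 - pm) * (1 - pd))
        return d / dmax if dmax > 0 else 0.0


def haplotype_freqs(marker_maf: float, daf: float, dprime: float) -> HaplotypeFreqs:
    """Haplotype frequencies with the "1" allele coupled to the risk allele.

    ``D = D'·Dmax`` with ``Dmax = min(pm(1−pd), (1−pm)pd)``; coupling is
    positive so that the marker tags the risk allele (the sign is
    irrelevant to two-sided tests).
    """
    if not (0.0 < marker_maf < 1.0 and 0.0 < daf < 1.0):
        raise ValueError("allele frequencies must be in (0, 1)")
    if not 0.0 <= dprime <= 1.0:
        raise ValueError("dprime must be in [0, 1]")
    dmax = min(marker_maf * (1.0 - daf), (1.0 - marker_maf) * daf)
    d = dprime * dmax
    hf = HaplotypeFreqs(
        q11=marker_maf * daf + d,
        q10=marker_maf * (1.0 - daf) - d,
        q01=(1.0 - marker_maf) * daf - d,
        q00=(1.0 - marker_maf) * (1.0 - daf) + d,
    )
    if min(hf.as_probs()) < -1e-12:
        raise ValueError("negative haplotype frequency")
    return hf


def prevalence(model: GeneticModel) -> float:
    """Population disease prevalence K implied by the model under HWE.

    ``K = f0(1−p)² + 2 f1 p(1−p) + f2 p²`` with p the disease allele
    frequency.
    """
    p = model.daf
    return model.f0 * (1 - p) ** 2 + model.f1 * 2 * p * (1 - p) + model.f2 * p**2


def _model_haplotypes(model: GeneticModel) -> np.ndarray:
    return haplotype_freqs(model.maf, model.daf, model.dprime).as_probs()


def simulate_trios(
    model: GeneticModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` case-parent trios conditional on an affected offspring.

    Returns ``(father_g, mother_g, child_g)`` marker genotype arrays.
    Rejection sampling: parental haplotypes are drawn i.i.d. from the
    model's haplotype frequencies, one haplotype per parent is
    transmitted uniformly at random, and the trio is accepted with
    probability equal to the offspring's penetrance. The acceptance rate
    is the population prevalence.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    probs = _model_haplotypes(model)
    pen = model.penetrances
    accept_rate = max(prevalence(model), 1.0 / MAX_REJECTION_ATTEMPTS)
    out_f: list[np.ndarray] = []
    out_m: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    need = n
    attempts = 0
    while need > 0:
        k = min(max(int(need / accept_rate * 1.25), 256), 4_000_000)
        attempts += k
        if attempts > MAX_REJECTION_ATTEMPTS * max(n, 1):
            raise RuntimeError(
                "rejection sampling did not terminate; penetrances may be ~0"
            )
        hap = rng.choice(4, size=(k, 4), p=probs)  # father x2, mother x2
        which_f = rng.integers(0, 2, size=k)
        which_m = rng.integers(0, 2, size=k)
        child_f = hap[np.arange(k), which_f]
        child_m = hap[np.arange(k), 2 + which_m]
        child_d = _DISEASE[child_f] + _DISEASE[child_m]
        accepted = rng.random(k) < pen[child_d]
        out_f.append(_MARKER[hap[accepted, 0]] + _MARKER[hap[accepted, 1]])
        out_m.append(_MARKER[hap[accepted, 2]] + _MARKER[hap[accepted, 3]])
        out_c.append(_MARKER[child_f[accepted]] + _MARKER[child_m[accepted]])
        need -= int(accepted.sum())
    father = np.concatenate(out_f)[:n].astype(np.int8)
    mother = np.concatenate(out_m)[:n].astype(np.int8)
    child = np.concatenate(out_c)[:n].astype(np.int8)
    return father, mother, child


def simulate_trio(model: GeneticModel, rng: np.random.Generator) -> TrioRecord:
    """Draw a single ascertained case-parent trio."""
    f, m, c = simulate_trios(model, 1, rng)
    return TrioRecord(int(f[0]), int(m[0]), int(c[0]))


def simulate_controls(
    model: GeneticModel,
    n: int,
    rng: np.random.Generator,
    mode: ControlMode = "population",
) -> np.ndarray:
    """Draw ``n`` control marker genotypes.

    ``mode="population"`` samples individuals from the general population
    (marker genotypes HWE at the marker MAF); ``mode="unaffected"``
    additionally rejection-samples on not being affected, which slightly
    depletes the risk-tagging allele.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    probs = _model_haplotypes(model)
    if mode == "population":
        hap = rng.choice(4, size=(n, 2), p=probs)
        return (_MARKER[hap[:, 0]] + _MARKER[hap[:, 1]]).astype(np.int8)
    if mode != "unaffected":
        raise ValueError(f"unknown control mode {mode!r}")
    pen = model.penetrances
    out: list[np.ndarray] = []
    need = n
    attempts = 0
    while need > 0:
        k = min(max(int(need * 1.25), 256), 4_000_000)
        attempts += k
        if attempts > MAX_REJECTION_ATTEMPTS * max(n, 1):
            raise RuntimeError("rejection sampling did not terminate")
        hap = rng.choice(4, size=(k, 2), p=probs)
        d = _DISEASE[hap[:, 0]] + _DISEASE[hap[:, 1]]
        accepted = rng.random(k) < 1.0 - pen[d]
        out.append(_MARKER[hap[accepted, 0]] + _MARKER[hap[accepted, 1]])
        need -= int(accepted.sum())
    return np.concatenate(out)[:n].astype(np.int8)


def simulate_control(
    model: GeneticModel, rng: np.random.Generator, mode: ControlMode = "population"
) -> int:
    """Draw a single control's marker allele count."""
    return int(simulate_controls(model, 1, rng, mode)[0])


def simulate_null_batch(
    maf: float, n_trios: int, n_controls: int, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized no-association replicates.

    Under the null there is no disease locus: parents are HWE(maf),
    offspring receive one uniformly chosen allele from each parent, and
    controls are HWE(maf). Returns ``(father_g, mother_g, child_g,
    control_g)`` with shapes ``(n_reps, n_trios)`` ×3 and
    ``(n_reps, n_controls)``.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    shape = (n_reps, n_trios)
    father = rng.binomial(2, maf, size=shape).astype(np.int8)
    mother = rng.binomial(2, maf, size=shape).astype(np.int8)
    # transmitted allele per parent: Bernoulli(g/2) given parental genotype
    child = rng.binomial(1, father / 2.0).astype(np.int8) + rng.binomial(
        1, mother / 2.0
    ).astype(np.int8)
    controls = rng.binomial(2, maf, size=(n_reps, n_controls)).astype(np.int8)
    return father, mother, child, controls


def simulate_null_dataset(
    maf: float, n_trios: int, n_controls: int, rng: np.random.Generator
) -> MixedDataset:
    """One no-association replicate as a :class:`MixedDataset`."""
    f, m, c, s = simulate_null_batch(maf, n_trios, n_controls, 1, rng)
    return MixedDataset(f[0], m[0], c[0], s[0])


def simulate_alt_dataset(
    model: GeneticModel,
    n_trios: int,
    n_controls: int,
    rng: np.random.Generator,
    control_mode: ControlMode = "population",
) -> MixedDataset:
    """One replicate under the alternative: ascertained trios + controls."""
    if n_trios < 1 or n_controls < 1:
        raise ValueError("need at least one trio and one control")
    f, m, c = simulate_trios(model, n_trios, rng)
    s = simulate_controls(model, n_controls, rng, control_mode)
    return MixedDataset(f, m, c, s)
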