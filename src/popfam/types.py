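"""Core data containers: trios, mixed trio/control datasets, test results.

Genotypes are throughout coded as counts of the "1" allele (by convention
the minor allele of the marker), so each genotype is an integer in
``{0, 1, 2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MendelianError",
    "TrioRecord",
    "MixedDataset",
    "TestResult",
]


class MendelianError(ValueError):
    """Raised when a trio's genotypes are incompatible with Mendelian
    transmission (e.g. both parents homozygous "0" but the child carries
    a "1" allele)."""


def _check_genotype(g: int, who: str) -> int:
    g = int(g)
    if g not in (0, 1, 2):
        raise ValueError(f"{who} genotype must be in {{0, 1, 2}}, got {g}")
    return g


@dataclass(frozen=True)
class TrioRecord:
    """A case-parent trio at a single biallelic marker.

    Attributes
    ----------
    father_g, mother_g, child_g:
        Counts of the "1" allele carried by each member, in {0, 1, 2}.
    h:
        Number of heterozygous parents (derived), in {0, 1, 2}. Only
        heterozygous parents are informative about transmission.
    t:
        Number of "1" alleles transmitted from heterozygous parents to the
        affected child (derived). Because every homozygous "1/1" parent
        transmits exactly one "1" allele and every homozygous "0/0" parent
        transmits none, ``t = child_g - #{parents with genotype 2}`` and is
        uniquely determined by the three genotypes; no phasing is required.
    """

    father_g: int
    mother_g: int
    child_g: int
    h: int = field(init=False)
    t: int = field(init=False)

    def __post_init__(self) -> None:
        f = _check_genotype(self.father_g, "father")
        m = _check_genotype(self.mother_g, "mother")
        c = _check_genotype(self.child_g, "child")
        h = (f == 1) + (m == 1)
        t = c - ((f == 2) + (m == 2))
        if not 0 <= t <= h:
            raise MendelianError(
                f"trio ({f}, {m}, {c}) is Mendelian-inconsistent: "
                f"implied transmissions t={t} outside [0, {h}]"
            )
        object.__setattr__(self, "h", int(h))
        object.__setattr__(self, "t", int(t))


class MixedDataset:
    """A set of case-parent trios plus unrelated controls at one marker.

    Internally stores genotypes as small integer arrays; the per-trio
    heterozygous-parent counts ``h`` and transmission counts ``t`` are
    derived on construction, and Mendelian consistency is enforced.

    Parameters
    ----------
    father_g, mother_g, child_g:
        Equal-length sequences of trio genotypes (allele-"1" counts).
    control_g:
        Genotypes of unrelated controls.
    extra_case_g:
        Genotypes of affected individuals without usable parental
        genotypes; they contribute to the population component only.
    """

    def __init__(
        self,
        father_g: Sequence[int] | np.ndarray,
        mother_g: Sequence[int] | np.ndarray,
        child_g: Sequence[int] | np.ndarray,
        control_g: Sequence[int] | np.ndarray,
        extra_case_g: Sequence[int] | np.ndarray = (),
    ) -> None:
        self.father_g = np.asarray(father_g, dtype=np.int8)
        self.mother_g = np.asarray(mother_g, dtype=np.int8)
        self.child_g = np.asarray(child_g, dtype=np.int8)
        self.control_g = np.asarray(control_g, dtype=np.int8)
        self.extra_case_g = np.asarray(extra_case_g, dtype=np.int8)
        if not (len(self.father_g) == len(self.mother_g) == len(self.child_g)):
            raise ValueError("trio genotype arrays must have equal length")
        for name, arr in (
            ("father_g", self.father_g),
            ("mother_g", self.mother_g),
            ("child_g", self.child_g),
            ("control_g", self.control_g),
            ("extra_case_g", self.extra_case_g),
        ):
            if arr.size and (arr.min() < 0 or arr.max() > 2):
                raise ValueError(f"{name} contains genotypes outside {{0, 1, 2}}")
        self.h = ((self.father_g == 1).astype(np.int8) + (self.mother_g == 1))
        self.t = self.child_g - (
            (self.father_g == 2).astype(np.int8) + (self.mother_g == 2)
        )
        bad = (self.t < 0) | (self.t > self.h)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise MendelianError(
                f"trio {idx} is Mendelian-inconsistent: "
                f"({self.father_g[idx]}, {self.mother_g[idx]}, {self.child_g[idx]})"
            )

    @classmethod
    def from_trios(
        cls, trios: Iterable[TrioRecord], control_g: Sequence[int] | np.ndarray
    ) -> "MixedDataset":
        trios = list(trios)
        return cls(
            [tr.father_g for tr in trios],
            [tr.mother_g for tr in trios],
            [tr.child_g for tr in trios],
            control_g,
        )

    # -- derived scalars ---------------------------------------------------

    @property
    def n_trios(self) -> int:
        """N, the number of case-parent trios."""
        return len(self.child_g)

    @property
    def n_controls(self) -> int:
        """M, the number of unrelated controls."""
        return len(self.control_g)

    @property
    def case_g(self) -> np.ndarray:
        """Case genotypes R_j: trio offspring plus parentless cases."""
        if self.extra_case_g.size:
            return np.concatenate([self.child_g, self.extra_case_g])
        return self.child_g

    @property
    def n_cases(self) -> int:
        """Total cases entering the population component."""
        return len(self.child_g) + len(self.extra_case_g)

    @property
    def H(self) -> int:
        """Total heterozygous parents across all trios (0 <= H <= 2N)."""
        return int(self.h.sum())

    @property
    def X(self) -> int:
        """Number of trios with at least one heterozygous parent."""
        return int((self.h >= 1).sum())

    @property
    def T_sum(self) -> int:
        """Total "1" alleles transmitted from heterozygous parents."""
        return int(self.t.sum())

    def trios(self) -> list[TrioRecord]:
        return [
            TrioRecord(int(f), int(m), int(c))
            for f, m, c in zip(self.father_g, self.mother_g, self.child_g)
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MixedDataset(N={self.n_trios}, M={self.n_controls}, "
            f"H={self.H}, X={self.X})"
        )


@dataclass(frozen=True)
class TestResult:
    """Result of the combined association test at one marker.

    ``P_stat`` is the population-based trend statistic, ``F_stat`` the
    family-based Wald transmission statistic, ``z`` the weighted
    combination, each standard normal under the null. ``tau`` is the null
    covariance between the standardized components induced by the shared
    cases.
    """

    P_stat: float
    F_stat: float
    w: float
    tau: float
    z: float
    p_value: float
    N: int
    M: int
    H: int
    X: int
    variance_mode: str
    sigma2: float
    maf_hat: float
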