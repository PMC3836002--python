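"""Whitespace-delimited pedigree (PED/MAP) reading and writing.

The classic linkage dialect: each PED row is
``family_id individual_id father_id mother_id sex phenotype`` followed by
one allele pair per marker (allele codes ``1``/``2`` or ``A,C,G,T``;
``0`` = missing), with a companion MAP file of
``chromosome marker_id genetic_distance position``. Phenotype 2 =
affected, 1 = unaffected, 0/-9 = missing.

Cohort assembly: an affected individual whose two parents both appear in
the same family forms a case-parent trio; unaffected founders unrelated
to any trio are controls. The "1" allele counted by the statistics is
the minor allele of each marker in the pooled sample (ties broken by
allele-code order).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import MendelianError, MixedDataset

__all__ = ["Individual", "Cohort", "read_ped", "write_ped", "cohort_from_datasets"]

logger = logging.getLogger(__name__)

MISSING_PHENO = {"0", "-9"}


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: str
    phenotype: str  # "1" unaffected, "2" affected, "0"/"-9" missing
    alleles: list[tuple[str, str]]  # one pair per marker, "0" = missing

    @property
    def affected(self) -> bool:
        return self.phenotype == "2"

    @property
    def unaffected(self) -> bool:
        return self.phenotype == "1"

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass
class Cohort:
    """Individuals plus marker metadata, with trio/control classification."""

    individuals: list[Individual]
    markers: pd.DataFrame  # columns: chrom, marker_id, cm, pos

    def __post_init__(self) -> None:
        by_key = {}
        for ind in self.individuals:
            key = (ind.family_id, ind.individual_id)
            if key in by_key:
                raise ValueError(f"duplicate individual {key}")
            by_key[key] = ind
        self._by_key = by_key
        # trios: affected with both parents present in the family
        self.trio_members: list[tuple[Individual, Individual, Individual]] = []
        trio_people: set[tuple[str, str]] = set()
        for ind in self.individuals:
            if not ind.affected or ind.is_founder:
                continue
            fa = by_key.get((ind.family_id, ind.father_id))
            mo = by_key.get((ind.family_id, ind.mother_id))
            if fa is None or mo is None:
                logger.warning(
                    "affected %s/%s lacks in-file parents; skipped",
                    ind.family_id, ind.individual_id,
                )
                continue
            self.trio_members.append((fa, mo, ind))
            trio_people.update(
                {(p.family_id, p.individual_id) for p in (fa, mo, ind)}
            )
        # founders who are somebody's parent are relatives, not controls
        parent_keys = {
            (ind.family_id, pid)
            for ind in self.individuals
            for pid in (ind.father_id, ind.mother_id)
            if pid != "0"
        }
        self.controls: list[Individual] = [
            ind
            for ind in self.individuals
            if ind.unaffected
            and ind.is_founder
            and (ind.family_id, ind.individual_id) not in trio_people
            and (ind.family_id, ind.individual_id) not in parent_keys
        ]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def minor_allele(self, marker_index: int) -> str | None:
        """Rarer allele code in the pooled sample; ties by code order."""
        counts: Counter[str] = Counter()
        for ind in self.individuals:
            for a in ind.alleles[marker_index]:
                if a != "0":
                    counts[a] += 1
        if not counts:
            return None
        if len(counts) == 1:
            return sorted(counts)[0]
        return min(sorted(counts), key=lambda a: counts[a])

    def dataset(self, marker_index: int, strict: bool = False) -> MixedDataset:
        """Per-marker mixed dataset of minor-allele counts.

        A trio with a missing parental genotype contributes nothing to
        the family component, but its genotyped child still enters the
        population component as a parentless case (logged). Controls
        missing the marker are dropped. Mendelian-inconsistent trios are
        dropped with a warning, or raise when ``strict``.
        """
        minor = self.minor_allele(marker_index)

        def count(ind: Individual) -> int | None:
            a, b = ind.alleles[marker_index]
            if a == "0" or b == "0":
                return None
            return (a == minor) + (b == minor)

        fgs, mgs, cgs = [], [], []
        extra_cases: list[int] = []
        for fa, mo, ch in self.trio_members:
            g = (count(fa), count(mo), count(ch))
            if None in g:
                if g[2] is not None:
                    extra_cases.append(g[2])
                logger.warning(
                    "trio %s/%s missing genotypes at marker %d; "
                    "excluded from the family component",
                    ch.family_id, ch.individual_id, marker_index,
                )
                continue
            f, m, c = g
            t = c - ((f == 2) + (m == 2))
            h = (f == 1) + (m == 1)
            if not 0 <= t <= h:
                msg = (
                    f"Mendelian inconsistency in trio {ch.family_id}/"
                    f"{ch.individual_id} at marker {marker_index}"
                )
                if strict:
                    raise MendelianError(msg)
                logger.warning("%s; trio dropped", msg)
                continue
            fgs.append(f)
            mgs.append(m)
            cgs.append(c)
        controls = [g for g in (count(c) for c in self.controls) if g is not None]
        return MixedDataset(fgs, mgs, cgs, controls, extra_cases)


def read_ped(ped_path, map_path) -> Cohort:
    """Parse PED + MAP files into a :class:`Cohort`."""
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        names=["chrom", "marker_id", "cm", "pos"],
        dtype=str,
        comment="#",
    )
    n_markers = len(markers)
    individuals: list[Individual] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(fields)}"
                )
            alleles = []
            for j in range(n_markers):
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                for code in (a, b):
                    if code not in {"0", "1", "2", "A", "C", "G", "T"}:
                        raise ValueError(
                            f"{ped_path}:{lineno}: bad allele code {code!r}"
                        )
                alleles.append((a, b))
            individuals.append(Individual(*fields[:6], alleles))
    return Cohort(individuals, markers)


def write_ped(cohort: Cohort, ped_path, map_path) -> None:
    """Write a cohort back to PED + MAP text files."""
    with open(map_path, "w") as fh:
        for _, row in cohort.markers.iterrows():
            fh.write(f"{row.chrom}\t{row.marker_id}\t{row.cm}\t{row.pos}\n")
    with open(ped_path, "w") as fh:
        for ind in cohort.individuals:
            cells = [
                ind.family_id, ind.individual_id, ind.father_id,
                ind.mother_id, ind.sex, ind.phenotype,
            ]
            for a, b in ind.alleles:
                cells.extend([a, b])
            fh.write("\t".join(cells) + "\n")


def _alleles_from_count(g: int) -> tuple[str, str]:
    # minor allele written as "1", major as "2"
    return ("1", "1") if g == 2 else (("1", "2") if g == 1 else ("2", "2"))


def cohort_from_datasets(
    datasets: Iterable[MixedDataset],
    marker_ids: Iterable[str] | None = None,
) -> Cohort:
    """Assemble a cohort from per-marker datasets sharing individuals.

    All datasets must have identical trio and control counts (the same
    people typed at each marker). Trios become three-person families
    (founder parents + affected child); controls become unaffected
    single founders.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets")
    N = datasets[0].n_trios
    M = datasets[0].n_controls
    if any(d.n_trios != N or d.n_controls != M for d in datasets):
        raise ValueError("datasets disagree on sample sizes")
    if marker_ids is None:
        marker_ids = [f"snp{j + 1}" for j in range(len(datasets))]
    marker_ids = list(marker_ids)
    markers = pd.DataFrame(
        {
            "chrom": "1",
            "marker_id": marker_ids,
            "cm": "0",
            "pos": [str(j + 1) for j in range(len(datasets))],
        }
    )
    individuals = []
    for i in range(N):
        fid = f"fam{i + 1}"
        trio_alleles = [
            (
                _alleles_from_count(int(d.father_g[i])),
                _alleles_from_count(int(d.mother_g[i])),
                _alleles_from_count(int(d.child_g[i])),
            )
            for d in datasets
        ]
        individuals.append(
            Individual(fid, "dad", "0", "0", "1", "1", [a[0] for a in trio_alleles])
        )
        individuals.append(
            Individual(fid, "mom", "0", "0", "2", "1", [a[1] for a in trio_alleles])
        )
        individuals.append(
            Individual(fid, "kid", "dad", "mom", "0", "2", [a[2] for a in trio_alleles])
        )
    for k in range(M):
        individuals.append(
            Individual(
                f"ctl{k + 1}", "1", "0", "0", "0", "1",
                [_alleles_from_count(int(d.control_g[k])) for d in datasets],
            )
        )
    return Cohort(individuals, markers)
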