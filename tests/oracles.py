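"""Independent brute-force references used to validate the implementation.

Everything here enumerates small discrete spaces directly (allele
phases, haplotype configurations) and never calls the code under test.
"""

from itertools import product

import numpy as np

#: haplotypes coded (marker allele, disease allele)
HAPLOTYPES = [(1, 1), (1, 0), (0, 1), (0, 0)]


def phase_enumeration(father_g, mother_g, child_g):
    """All transmission-consistent phase assignments of a trio.

    Enumerates ordered parental allele pairs compatible with each
    genotype and the four transmission choices; returns the list of
    (h, t) pairs over assignments reproducing the child genotype, where
    h counts heterozygous parents and t the "1" alleles the child
    received from them.
    """

    def phases(g):
        return [(a, g - a) for a in (0, 1) if 0 <= g - a <= 1]

    results = []
    for fa in phases(father_g):
        for mo in phases(mother_g):
            for i, j in product((0, 1), repeat=2):
                if fa[i] + mo[j] != child_g:
                    continue
                h = (father_g == 1) + (mother_g == 1)
                t = (fa[i] if father_g == 1 else 0) + (mo[j] if mother_g == 1 else 0)
                results.append((h, t))
    return results


def exact_trio_distribution(marker_maf, daf, dprime, penetrances):
    """Exact genotype-triple distribution of an ascertained trio.

    Enumerates the 4^4 ordered parental haplotype configurations and the
    4 transmission choices, weighting by haplotype frequencies and the
    offspring's penetrance. Returns a dict mapping (father_g, mother_g,
    child_g) marker genotypes to conditional probabilities (summing
    to 1).
    """
    dmax = min(marker_maf * (1 - daf), (1 - marker_maf) * daf)
    d = dprime * dmax
    q = {
        (1, 1): marker_maf * daf + d,
        (1, 0): marker_maf * (1 - daf) - d,
        (0, 1): (1 - marker_maf) * daf - d,
        (0, 0): (1 - marker_maf) * (1 - daf) + d,
    }
    pen = np.asarray(penetrances)
    dist: dict[tuple[int, int, int], float] = {}
    total = 0.0
    for f1, f2, m1, m2 in product(HAPLOTYPES, repeat=4):
        w_par = q[f1] * q[f2] * q[m1] * q[m2]
        for cf, cm in product((f1, f2), (m1, m2)):
            w = w_par * 0.25 * pen[cf[1] + cm[1]]
            key = (f1[0] + f2[0], m1[0] + m2[0], cf[0] + cm[0])
            dist[key] = dist.get(key, 0.0) + w
            total += w
    return {k: v / total for k, v in dist.items()}


def exact_control_maf(marker_maf, daf, dprime, penetrances, mode):
    """Exact marker allele frequency among controls."""
    dmax = min(marker_maf * (1 - daf), (1 - marker_maf) * daf)
    d = dprime * dmax
    q = {
        (1, 1): marker_maf * daf + d,
        (1, 0): marker_maf * (1 - daf) - d,
        (0, 1): (1 - marker_maf) * daf - d,
        (0, 0): (1 - marker_maf) * (1 - daf) + d,
    }
    pen = np.asarray(penetrances)
    num = den = 0.0
    for h1, h2 in product(HAPLOTYPES, repeat=2):
        w = q[h1] * q[h2]
        if mode == "unaffected":
            w *= 1.0 - pen[h1[1] + h2[1]]
        num += w * (h1[0] + h2[0])
        den += w
    return num / den / 2.0
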