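"""Summary statistics on masked, haploidized genotype matrices.

The statistic vector summarises a multi-locus dataset by the mean and
variance across loci of nucleotide diversity (per species and pooled),
Tajima's D (per species) and Hudson's F_ST, plus the proportions of
shared, fixed and private polymorphisms pooled over all SNPs.  All
statistics honour per-site missingness: a site enters a statistic only if
it is *assayable*, i.e. has at least ``min_called`` called (non-missing)
entries in every species the statistic involves — the post-haploidization
mirror of the coverage filter applied to the observed data.

Estimator notes.  Per-site heterozygosity uses the unbiased form
2*p*q*n/(n-1) with the per-site called sample size n.  Tajima's D
evaluates the 1989 constants at the modal called sample size of the locus.
F_ST is Hudson's 1 - Hw/Hb with within- and between-species
heterozygosities averaged over sites before the ratio (ratio of averages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .simulate import MISSING, HaplotypeMatrix, SimulatedDataset

__all__ = [
    "STAT_NAMES",
    "STAT_VERSION",
    "SummaryStatisticsVector",
    "nucleotide_diversity",
    "tajimas_d",
    "fst",
    "snp_partition",
    "locus_statistics",
    "summarize_dataset",
]

#: Fixed, versioned order of the statistic vector.  Observed and simulated
#: vectors must be computed with the same manifest version.
STAT_VERSION = "1"
STAT_NAMES: Tuple[str, ...] = (
    "pi_coll_mean",
    "pi_coll_var",
    "pi_pied_mean",
    "pi_pied_var",
    "pi_pooled_mean",
    "pi_pooled_var",
    "tajd_coll_mean",
    "tajd_coll_var",
    "tajd_pied_mean",
    "tajd_pied_var",
    "fst_mean",
    "fst_var",
    "prop_shared",
    "prop_fixed",
    "prop_private_coll",
    "prop_private_pied",
)


@dataclass
class SummaryStatisticsVector:
    """Named, ordered summary-statistic values for one dataset."""

    values: np.ndarray
    names: Tuple[str, ...] = STAT_NAMES
    version: str = STAT_VERSION
    n_loci_used: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("statistic vector length mismatch")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _called_counts(alleles: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column number of called entries and derived-allele count."""
    called = alleles != MISSING
    n = called.sum(axis=0)
    k = np.where(called, alleles, 0).sum(axis=0)
    return n, k


def _site_heterozygosity(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*p*q*n/(n-1) from counts."""
    het = np.zeros_like(n, dtype=float)
    ok = n >= 2
    nf = n[ok].astype(float)
    p = k[ok] / nf
    het[ok] = 2.0 * p * (1.0 - p) * nf / (nf - 1.0)
    return het


def nucleotide_diversity(
    alleles: np.ndarray, site_ok: np.ndarray, n_assayable: int
) -> float:
    """Mean pairwise difference per assayable site.

    ``alleles`` is one species' (or the pooled) haploid matrix with -1 for
    missing; ``site_ok`` flags the assayable columns; ``n_assayable`` is
    the total number of assayable sites including monomorphic ones.
    """
    if n_assayable <= 0:
        raise ValueError("no assayable sites")
    n, k = _called_counts(alleles[:, site_ok])
    return float(_site_heterozygosity(n, k).sum() / n_assayable)


def _tajima_constants(n: int) -> Tuple[float, float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(alleles: np.ndarray, site_ok: np.ndarray) -> float:
    """Tajima's D for one species at one locus; NaN when undefined.

    The constants are evaluated at the modal called sample size among the
    assayable segregating sites; the pairwise-difference total and S are
    restricted to assayable sites.  Undefined (NaN) when there are no
    segregating assayable sites or the modal sample size is below 4.
    """
    n, k = _called_counts(alleles[:, site_ok])
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n_mode = int(np.bincount(n[seg]).argmax())
    if n_mode < 4:
        return float("nan")
    pi_total = float(_site_heterozygosity(n[seg], k[seg]).sum())
    a1, e1, e2 = _tajima_constants(n_mode)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1.0))
    if denom == 0:
        return float("nan")
    return float((pi_total - S / a1) / denom)


def fst(
    alleles_a: np.ndarray, alleles_b: np.ndarray, site_ok: np.ndarray
) -> float:
    """Hudson's F_ST = 1 - Hw/Hb over jointly assayable sites; NaN if Hb=0.

    Hw averages the two species' per-site heterozygosities; Hb is the mean
    between-species difference p_a*(1-p_b) + p_b*(1-p_a).  Sites
    monomorphic for the same allele in both species contribute zero to both
    sums and can be skipped, so only segregating columns matter.
    """
    na, ka = _called_counts(alleles_a[:, site_ok])
    nb, kb = _called_counts(alleles_b[:, site_ok])
    ok = (na >= 2) & (nb >= 2)
    na, ka, nb, kb = na[ok], ka[ok], nb[ok], kb[ok]
    pa = ka / na
    pb = kb / nb
    hw = 0.5 * (_site_heterozygosity(na, ka) + _site_heterozygosity(nb, kb))
    hb = pa * (1.0 - pb) + pb * (1.0 - pa)
    hb_sum = hb.sum()
    if hb_sum == 0:
        return float("nan")
    return float(1.0 - hw.sum() / hb_sum)


def snp_partition(
    alleles_a: np.ndarray, alleles_b: np.ndarray, site_ok: np.ndarray
) -> np.ndarray:
    """Per-site SNP counts: (shared, fixed, private_a, private_b).

    A SNP is any jointly assayable site that is not monomorphic for the
    same allele in both samples.  Segregating in both samples: shared;
    monomorphic for different alleles: fixed (in these samples, not in the
    species); segregating in exactly one: private to it.
    """
    na, ka = _called_counts(alleles_a[:, site_ok])
    nb, kb = _called_counts(alleles_b[:, site_ok])
    seg_a = (ka > 0) & (ka < na)
    seg_b = (kb > 0) & (kb < nb)
    mono_a_allele = np.where(ka == 0, 0, np.where(ka == na, 1, -9))
    mono_b_allele = np.where(kb == 0, 0, np.where(kb == nb, 1, -9))
    shared = seg_a & seg_b
    fixed = (
        (mono_a_allele >= 0)
        & (mono_b_allele >= 0)
        & (mono_a_allele != mono_b_allele)
    )
    private_a = seg_a & ~seg_b
    private_b = seg_b & ~seg_a
    return np.array(
        [shared.sum(), fixed.sum(), private_a.sum(), private_b.sum()], dtype=np.int64
    )


def locus_statistics(
    matrix: HaplotypeMatrix,
) -> Dict[str, float | np.ndarray]:
    """All per-locus statistics for one haploidized matrix."""
    if not matrix.haploid:
        raise ValueError("statistics are defined on haploidized matrices")
    min_called = matrix.min_called
    coll = matrix.species_rows("coll")
    pied = matrix.species_rows("pied")
    n_c, _ = _called_counts(coll)
    n_p, _ = _called_counts(pied)
    ok_c = n_c >= min_called
    ok_p = n_p >= min_called
    ok_joint = ok_c & ok_p

    out: Dict[str, float | np.ndarray] = {}
    out["pi_coll"] = nucleotide_diversity(coll, ok_c, matrix.n_assayable["coll"])
    out["pi_pied"] = nucleotide_diversity(pied, ok_p, matrix.n_assayable["pied"])
    out["pi_pooled"] = nucleotide_diversity(
        matrix.alleles, ok_joint, matrix.n_assayable["joint"]
    )
    out["tajd_coll"] = tajimas_d(coll, ok_c)
    out["tajd_pied"] = tajimas_d(pied, ok_p)
    out["fst"] = fst(coll, pied, ok_joint)
    out["partition"] = snp_partition(coll, pied, ok_joint)
    return out


def summarize_dataset(dataset: SimulatedDataset) -> SummaryStatisticsVector:
    """Aggregate per-locus statistics into the dataset-level vector.

    Means and sample variances (denominator n-1) are taken across loci;
    loci where a statistic is undefined (monomorphic loci for D, zero
    between-species difference for F_ST) are excluded from that
    statistic's mean and variance, with the retained counts reported.
    SNP-partition proportions are pooled over all loci's SNPs.
    """
    if len(dataset.loci) < 2:
        raise ValueError("need at least two loci to form means and variances")
    per_locus = [locus_statistics(m) for m in dataset.loci]

    values: List[float] = []
    used: Dict[str, int] = {}
    for key in ("pi_coll", "pi_pied", "pi_pooled", "tajd_coll", "tajd_pied", "fst"):
        x = np.array([p[key] for p in per_locus], dtype=float)
        x = x[~np.isnan(x)]
        used[key] = len(x)
        if len(x) == 0:
            raise ValueError(f"statistic {key} undefined on every locus")
        values.append(float(x.mean()))
        values.append(float(x.var(ddof=1)) if len(x) > 1 else 0.0)

    counts = np.sum([p["partition"] for p in per_locus], axis=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no SNPs in dataset; partition undefined")
    values.extend((counts / total).tolist())
    return SummaryStatisticsVector(np.array(values), n_loci_used=used)
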