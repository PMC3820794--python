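"""Synthetic study data: coverage-driven masks and known-truth datasets.

The study's raw sequence data are not distributable, so everything the
pipeline consumes is emulated here: per-individual per-site sequencing
depths drawn from an over-dispersed count model at the study's mean
coverage, converted to missingness masks by the coverage filter (a
genotype is callable with at least ``min_reads`` reads; a site is
assayable for a species when at least ``min_individuals`` of its
individuals are callable), and loci rejected outright when more than
``max_locus_missing`` of their sites fail the joint filter — filtering,
not editing, mirroring the study's reduction from candidate to final loci.

Pseudo-observed datasets with known truth reuse the simulate module's
exact code path (simulate, mask transplant, haploidize), so the
bookkeeping applied to "observed" data is byte-identical to that applied
to reference-table simulations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .demographic_models import (
    GLOBAL_MEAN_RECOMBINATION,
    ParameterDraw,
    ScalingConvention,
    build_model,
    draw_model_parameters,
)
from .simulate import (
    HaplotypeMatrix,
    LocusSet,
    LocusSpec,
    SimulatedDataset,
    simulate_dataset,
)

__all__ = [
    "CoverageModel",
    "TruthRecord",
    "generate_masks",
    "generate_observed_dataset",
    "fixture_small",
    "FIXTURE_SEED",
]


@dataclass(frozen=True)
class CoverageModel:
    """Sequencing-depth model behind the missingness masks.

    Depths are negative-binomial with mean ``mean_depth`` and variance
    mean*(1 + dispersion): ``dispersion`` is the excess-variance ratio
    over Poisson (shape parameter mean/dispersion), capturing
    between-site and between-individual coverage heterogeneity.  The
    thresholds are the study's filter: >=3 reads to call a genotype, >=7
    callable individuals per species for a site, and at most 30% failed
    sites per retained locus.
    """

    mean_depth: float = 5.0
    dispersion: float = 0.5
    min_reads: int = 3
    min_individuals: int = 7
    max_locus_missing: float = 0.30

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0 < self.max_locus_missing < 1:
            raise ValueError("max_locus_missing must be in (0, 1)")

    def draw_depths(
        self, shape: Tuple[int, ...], rng: np.random.Generator
    ) -> np.ndarray:
        k = self.mean_depth / self.dispersion
        p = k / (k + self.mean_depth)
        return rng.negative_binomial(k, p, size=shape)


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of a pseudo-observed dataset: enough to regenerate it."""

    model_name: str
    values: Dict[str, float]
    root_seed: int
    locus_set_hash: str

    @property
    def digest(self) -> str:
        payload = json.dumps(
            {
                "model": self.model_name,
                "values": {k: repr(v) for k, v in sorted(self.values.items())},
                "root_seed": self.root_seed,
                "locus_set_hash": self.locus_set_hash,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def generate_masks(
    n_loci: int = 267,
    n_per_species: Tuple[int, int] = (10, 10),
    length: int = 2000,
    coverage: CoverageModel = CoverageModel(),
    rng: Optional[np.random.Generator] = None,
    r_mean: float = GLOBAL_MEAN_RECOMBINATION,
    r_log_sd: float = 0.6,
    max_reject_fraction: float = 0.99,
) -> LocusSet:
    """Generate a locus set with coverage-driven missingness masks.

    Per-locus local recombination-rate means are log-normal around
    ``r_mean`` (sigma ``r_log_sd`` on the log scale), emulating a
    recombination landscape.  A locus whose fraction of jointly
    non-assayable sites exceeds the threshold is rejected and redrawn;
    the emitted set satisfies both coverage thresholds by construction.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_loci <= 0 or length <= 0:
        raise ValueError("n_loci and length must be positive")
    n_total = sum(n_per_species)
    n_coll = n_per_species[0]
    loci = []
    rejections = 0
    attempts_budget = max(int(n_loci / (1.0 - max_reject_fraction)), n_loci + 10)
    # log-normal with the requested arithmetic mean
    mu_log = np.log(r_mean) - 0.5 * r_log_sd**2
    while len(loci) < n_loci:
        if rejections >= attempts_budget:
            raise RuntimeError(
                "coverage model inconsistent with thresholds: "
                f"{rejections} rejections for {len(loci)} accepted loci"
            )
        depths = coverage.draw_depths((n_total, length), rng)
        mask = depths < coverage.min_reads
        called_coll = (~mask[:n_coll]).sum(axis=0)
        called_pied = (~mask[n_coll:]).sum(axis=0)
        assayable = (called_coll >= coverage.min_individuals) & (
            called_pied >= coverage.min_individuals
        )
        missing_fraction = 1.0 - assayable.mean()
        local_r = float(np.exp(rng.normal(mu_log, r_log_sd)))
        if missing_fraction > coverage.max_locus_missing:
            rejections += 1
            continue
        loci.append(
            LocusSpec(
                locus_id=f"locus_{len(loci):04d}",
                length=length,
                local_r_mean=local_r,
                mask=mask,
                n_per_species=n_per_species,
            )
        )
    return LocusSet(loci=loci, n_per_species=n_per_species)


def generate_observed_dataset(
    model_name: str,
    locus_set: LocusSet,
    root_seed: int,
    truth: Optional[ParameterDraw] = None,
    scaling: ScalingConvention = ScalingConvention(),
    priors: Optional[Sequence] = None,
    min_called: int = 7,
    keep_raw: bool = False,
):
    """A pseudo-observed dataset with known truth, via the simulate path.

    When ``truth`` is None the parameters are drawn from the priors.  The
    returned record regenerates the dataset bit-identically from the same
    seed and locus set.  ``keep_raw`` additionally returns the diploid
    pre-haploidization matrices (for VCF export).
    """
    rng = np.random.default_rng(np.random.SeedSequence(root_seed))
    if truth is None:
        truth = draw_model_parameters(model_name, rng, scaling, priors=priors)
    model = build_model(model_name, truth, scaling)
    out = simulate_dataset(model, locus_set, rng, min_called, keep_raw=keep_raw)
    record = TruthRecord(
        model_name=model_name,
        values=dict(truth.values),
        root_seed=root_seed,
        locus_set_hash=locus_set.content_hash,
    )
    if keep_raw:
        dataset, raw = out
        return dataset, record, raw
    return out, record


FIXTURE_SEED = 20130719


def fixture_small() -> Tuple[SimulatedDataset, LocusSet, TruthRecord]:
    """A miniature deterministic dataset for hand-checkable statistics.

    Four loci of 200 bp with 4+4 diploid individuals under an
    isolation-constant-size history; the called-sample threshold is
    lowered to 2 to suit the tiny sample (4 is the smallest size at which
    Tajima's D is defined).  Every statistic on it is small enough to
    verify against exhaustive pairwise loops.
    """
    rng = np.random.default_rng(np.random.SeedSequence(FIXTURE_SEED))
    coverage = CoverageModel(mean_depth=6.0, dispersion=0.5, min_individuals=2)
    locus_set = generate_masks(
        n_loci=4,
        n_per_species=(4, 4),
        length=200,
        coverage=coverage,
        rng=rng,
    )
    # mutation rate well above the avian point estimate so that the tiny
    # loci carry a handful of SNPs each
    truth = ParameterDraw(
        "ICS",
        {
            "N_coll": 60_000.0,
            "N_pied": 40_000.0,
            "N_anc": 80_000.0,
            "T_split": 300_000.0,
            "mu": 1.0e-8,
            "r": 5.3e-8,
            "alpha": 3.0,
        },
    )
    dataset, record = generate_observed_dataset(
        "ICS",
        locus_set,
        root_seed=FIXTURE_SEED,
        truth=truth,
        min_called=2,
    )
    return dataset, locus_set, record
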