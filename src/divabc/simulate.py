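"""Coalescent simulation of masked, haploidized multi-locus datasets.

A dataset is a set of independent noncoding loci simulated under one
divergence history.  Each locus is an infinite-sites coalescent sample with
locus-specific mutation and recombination rates (Gamma-distributed around
dataset-level means), observed through the same per-individual missingness
masks as the study data and haploidized by sampling one allele per
individual per site — the mask-transplant idea: simulated data must be
filtered exactly like the observed data before any statistic is computed.

The per-locus simulator wraps msprime.  Because reference tables need
hundreds of thousands of tiny (<= 2 kb) loci, a cached fast path constructs
the low-level simulator from pre-converted demography ingredients, which is
byte-identical to ``msprime.sim_ancestry`` with the same seed (asserted in
the test suite) but roughly five times faster.  Mutations are dropped with
the binary infinite-sites model on a continuous genome, as in ms-family
simulators.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import msprime
import numpy as np
import pandas as pd
import tskit

from .demographic_models import (
    GLOBAL_MEAN_RECOMBINATION,
    DemographicModel,
    ParameterDraw,
    ScalingConvention,
    build_model,
    default_priors,
    draw_model_parameters,
)

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

__all__ = [
    "LocusSpec",
    "LocusSet",
    "HaplotypeMatrix",
    "SimulatedDataset",
    "DatasetRates",
    "LocusEngine",
    "draw_locus_rates",
    "simulate_locus",
    "apply_mask_and_haploidize",
    "simulate_dataset",
    "simulate_reference_table",
]


@dataclass
class LocusSpec:
    """One locus: its length, local recombination-rate mean and mask.

    ``mask`` is boolean with shape (n_individuals_total, length); True marks
    a genotype call that failed the coverage filter and is treated as
    missing for that individual at that site.  Individuals are ordered
    coll then pied.
    """

    locus_id: str
    length: int
    local_r_mean: float = GLOBAL_MEAN_RECOMBINATION
    mask: Optional[np.ndarray] = None
    n_per_species: Tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("locus length must be positive")
        if self.local_r_mean < 0:
            raise ValueError("negative recombination rate")
        n_total = sum(self.n_per_species)
        if self.mask is None:
            self.mask = np.zeros((n_total, self.length), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n_total, self.length):
            raise ValueError(
                f"mask shape {self.mask.shape} != ({n_total}, {self.length})"
            )

    def called_per_site(self, species: str) -> np.ndarray:
        """Number of called individuals per site for one species."""
        n_coll = self.n_per_species[0]
        rows = slice(0, n_coll) if species == "coll" else slice(n_coll, None)
        return (~self.mask[rows]).sum(axis=0)

    def assayable_sites(self, min_called: int) -> Dict[str, np.ndarray]:
        """Boolean per-site assayability for each species and jointly."""
        coll = self.called_per_site("coll") >= min_called
        pied = self.called_per_site("pied") >= min_called
        return {"coll": coll, "pied": pied, "joint": coll & pied}


@dataclass
class LocusSet:
    """An ordered collection of loci sharing one sample layout."""

    loci: List[LocusSpec]
    n_per_species: Tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus.n_per_species != self.n_per_species:
                raise ValueError("inconsistent individual counts across loci")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def content_hash(self) -> str:
        """Stable hash of locus lengths, rates and masks."""
        h = hashlib.sha256()
        for locus in self.loci:
            h.update(locus.locus_id.encode())
            h.update(np.int64(locus.length).tobytes())
            h.update(np.float64(locus.local_r_mean).tobytes())
            h.update(np.packbits(locus.mask).tobytes())
        return h.hexdigest()


@dataclass
class HaplotypeMatrix:
    """Biallelic alleles at segregating sites of one locus.

    Before haploidization rows are haploid lineages (two consecutive rows
    per diploid individual, coll first); afterwards rows are individuals
    and entries may be missing (-1).  ``positions`` are 0-based site indices
    within the locus.  ``n_assayable`` counts sites (monomorphic included)
    passing the per-species called-sample rule, as derived from the mask.
    """

    alleles: np.ndarray
    positions: np.ndarray
    length: int
    n_per_species: Tuple[int, int]
    haploid: bool
    n_assayable: Dict[str, int]
    min_called: int = 7

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions do not match allele columns")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def species_rows(self, species: str) -> np.ndarray:
        n_coll = self.n_per_species[0]
        k = n_coll if self.haploid else 2 * n_coll
        return self.alleles[:k] if species == "coll" else self.alleles[k:]

    @classmethod
    def from_called(
        cls,
        alleles: np.ndarray,
        length: int,
        n_per_species: Tuple[int, int],
        positions: Optional[np.ndarray] = None,
        min_called: int = 7,
    ) -> "HaplotypeMatrix":
        """Build a fully-called haploid matrix (tests, toy data).

        All unlisted sites are assumed called in every individual, so every
        site is assayable provided the sample sizes meet the threshold.
        """
        alleles = np.asarray(alleles, dtype=np.int8)
        if positions is None:
            positions = np.arange(alleles.shape[1])
        n_assayable = {
            "coll": length if n_per_species[0] >= min_called else 0,
            "pied": length if n_per_species[1] >= min_called else 0,
        }
        n_assayable["joint"] = min(n_assayable["coll"], n_assayable["pied"])
        return cls(
            alleles=alleles,
            positions=np.asarray(positions),
            length=length,
            n_per_species=n_per_species,
            haploid=True,
            n_assayable=n_assayable,
            min_called=min_called,
        )


@dataclass
class SimulatedDataset:
    """A multi-locus dataset simulated under one parameter draw."""

    model_name: str
    draw: Optional[ParameterDraw]
    loci: List[HaplotypeMatrix]

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class DatasetRates:
    """Dataset-level rate draws governing per-locus Gamma rates."""

    mean_mu: float
    mean_r: float
    alpha: float

    def __post_init__(self) -> None:
        if self.mean_mu <= 0 or self.mean_r <= 0:
            raise ValueError("rate means must be positive")
        if self.alpha <= 0:
            raise ValueError("Gamma shape must be positive")


def draw_locus_rates(
    rates: DatasetRates, locus: LocusSpec, rng: np.random.Generator
) -> Tuple[float, float]:
    """Draw per-locus mutation and recombination rates.

    Both are Gamma(shape=alpha, rate=alpha/mean): the mutation-rate mean is
    the dataset-level draw, while the recombination mean is the locus's
    local estimate rescaled by the dataset draw relative to the genome-wide
    mean, preserving the relative recombination landscape across loci.
    """
    mu = float(rng.gamma(rates.alpha, rates.mean_mu / rates.alpha))
    r_mean = locus.local_r_mean * rates.mean_r / GLOBAL_MEAN_RECOMBINATION
    r = float(rng.gamma(rates.alpha, r_mean / rates.alpha))
    return mu, r


# --------------------------------------------------------------------------
# Locus-level simulation engine
# --------------------------------------------------------------------------

try:  # pragma: no cover - exercised indirectly
    from msprime import _msprime as _ll
    from msprime import ancestry as _ancestry
    from msprime.mutations import BinaryMutationModel as _BinaryModel

    _HAVE_FAST_PATH = True
except ImportError:  # pragma: no cover
    _HAVE_FAST_PATH = False

_BLOCK_SIZE = 1024  # small allocation blocks: loci are tiny

# Initial-state ingredients that do not depend on demography parameters
# (sample nodes, gene-conversion map, coalescent model), cached per
# (length, sample layout) because reference tables construct one engine
# per parameter draw.
_TEMPLATE_CACHE: Dict[Tuple[float, Tuple[int, int]], dict] = {}


def _static_template(demography, samples, length: float, n_per_species):
    key = (length, n_per_species)
    tmpl = _TEMPLATE_CACHE.get(key)
    if tmpl is None:
        parsed = _ancestry._parse_sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=length,
            recombination_rate=0.0,
            random_seed=1,
            discrete_genome=False,
        )
        tmpl = {
            "tables_dict": parsed.copy_tables().asdict(),
            "models": parsed.models,
            "gc_map": parsed.gene_conversion_map,
            "binary_model": _BinaryModel(),
            "rmap_pos": np.array([0.0, float(length)]),
        }
        _TEMPLATE_CACHE[key] = tmpl
    return tmpl


class LocusEngine:
    """Simulates loci under one demography with per-locus rates.

    The engine converts the demography to its low-level representation
    once and reuses it for every locus, falling back to the public msprime
    API when the low-level interface is unavailable.  With a given seed
    the ancestry is identical between the two paths.
    """

    def __init__(
        self,
        model: DemographicModel,
        length: float,
        n_per_species: Tuple[int, int] = (10, 10),
        use_fast_path: bool = True,
    ):
        self.model = model
        self.length = float(length)
        self.n_per_species = n_per_species
        self.demography = model.to_msprime()
        self.samples = [
            msprime.SampleSet(n_per_species[0], population="coll", ploidy=2),
            msprime.SampleSet(n_per_species[1], population="pied", ploidy=2),
        ]
        self.use_fast_path = use_fast_path and _HAVE_FAST_PATH
        if self.use_fast_path:
            tmpl = _static_template(
                self.demography, self.samples, self.length, n_per_species
            )
            resolved = self.demography.validate()
            self._resolved = resolved
            self._tables_dict = tmpl["tables_dict"]
            self._ll_pop_conf = [p.asdict() for p in resolved.populations]
            self._ll_events = [e.get_ll_representation() for e in resolved.events]
            self._migration_matrix = resolved.migration_matrix
            self._models = tmpl["models"]
            self._gc_map = tmpl["gc_map"]
            self._binary_model = tmpl["binary_model"]
            self._rmap_pos = tmpl["rmap_pos"]

    def sim_ancestry(self, r: float, seed: int) -> tskit.TreeSequence:
        """Ancestry only; used by the path-equivalence test."""
        if not self.use_fast_path:
            return msprime.sim_ancestry(
                self.samples,
                demography=self.demography,
                sequence_length=self.length,
                recombination_rate=r,
                random_seed=seed,
                discrete_genome=False,
                record_provenance=False,
            )
        sim = self._make_sim(r, seed)
        sim.run()
        tables = tskit.TableCollection.fromdict(sim.tables.asdict())
        return tables.tree_sequence()

    def _make_sim(self, r: float, seed: int):
        ll_tables = _ll.LightweightTableCollection(self.length)
        ll_tables.fromdict(self._tables_dict)
        sim = _ancestry.Simulator.__new__(_ancestry.Simulator)
        _ll.Simulator.__init__(
            sim,
            tables=ll_tables,
            recombination_map={"position": self._rmap_pos, "rate": np.array([r])},
            start_time=-1,
            random_generator=_ll.RandomGenerator(seed),
            migration_matrix=self._migration_matrix,
            population_configuration=self._ll_pop_conf,
            demographic_events=self._ll_events,
            store_migrations=False,
            additional_nodes=0,
            coalescing_segments_only=True,
            num_labels=1,
            segment_block_size=_BLOCK_SIZE,
            avl_node_block_size=_BLOCK_SIZE,
            node_mapping_block_size=_BLOCK_SIZE,
            gene_conversion_rate=0.0,
            gene_conversion_tract_length=1.0,
            discrete_genome=False,
            ploidy=2,
            stop_at_local_mrca=True,
        )
        sim.end_time = np.inf
        sim.models = self._models
        sim.demography = self._resolved
        sim.gene_conversion_map = self._gc_map
        return sim

    def simulate(
        self, mu: float, r: float, seed: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """One locus: returns (haplotypes, site positions).

        ``haplotypes`` has shape (2*(n_coll+n_pied), S) with coll lineages
        first; positions are continuous in [0, length).
        """
        if mu < 0 or r < 0:
            raise ValueError("rates must be nonnegative")
        try:
            if self.use_fast_path:
                sim = self._make_sim(r, seed)
                sim.run()
                _ll.sim_mutations(
                    sim.tables,
                    sim.random_generator,
                    {"position": self._rmap_pos, "rate": np.array([mu])},
                    model=self._binary_model,
                    discrete_genome=False,
                )
                tables = tskit.TableCollection.fromdict(sim.tables.asdict())
                ts = tables.tree_sequence()
            else:
                anc = self.sim_ancestry(r, seed)
                ts = msprime.sim_mutations(
                    anc,
                    rate=mu,
                    model=msprime.BinaryMutationModel(),
                    discrete_genome=False,
                    random_seed=seed,
                )
        except Exception as exc:  # add model context, then re-raise
            raise RuntimeError(
                f"simulation failed for model {self.model.name} "
                f"(seed={seed}, mu={mu:.3g}, r={r:.3g}): {exc}"
            ) from exc
        genotypes = ts.genotype_matrix().T.astype(np.int8)
        positions = ts.sites_position
        return genotypes, positions


def simulate_locus(
    model: DemographicModel,
    locus: LocusSpec,
    mu_locus: float,
    r_locus: float,
    rng: np.random.Generator,
    n_per_species: Tuple[int, int] = (10, 10),
    engine: Optional[LocusEngine] = None,
) -> HaplotypeMatrix:
    """Simulate one locus and return the pre-haploidization matrix.

    Two haploid lineages per diploid individual; no missing data yet.
    """
    if engine is None:
        engine = LocusEngine(model, locus.length, n_per_species)
    seed = int(rng.integers(1, 2**31 - 1))
    genotypes, positions = engine.simulate(mu_locus, r_locus, seed)
    site_idx = np.minimum(np.floor(positions), locus.length - 1).astype(np.int64)
    return HaplotypeMatrix(
        alleles=genotypes,
        positions=site_idx,
        length=locus.length,
        n_per_species=n_per_species,
        haploid=False,
        n_assayable={
            "coll": locus.length,
            "pied": locus.length,
            "joint": locus.length,
        },
    )


def apply_mask_and_haploidize(
    matrix: HaplotypeMatrix,
    locus: LocusSpec,
    rng: np.random.Generator,
    min_called: int = 7,
) -> HaplotypeMatrix:
    """Transplant the locus mask onto simulated data, then haploidize.

    Every individualxsite cell flagged in the mask loses both alleles;
    each remaining diploid genotype is collapsed to one uniformly chosen
    allele.  Assayable-site totals (sites with at least ``min_called``
    called individuals per species, monomorphic sites included) are
    recomputed from the mask so that downstream statistics use the same
    denominators as for the observed data.
    """
    if matrix.haploid:
        raise ValueError("matrix is already haploidized")
    n_ind = sum(matrix.n_per_species)
    if matrix.alleles.shape[0] != 2 * n_ind:
        raise ValueError("expected two haplotypes per individual")
    if matrix.length != locus.length:
        raise ValueError("matrix and locus lengths differ")
    if locus.mask.shape != (n_ind, locus.length):
        raise ValueError("mask dimensions do not match the locus")

    S = matrix.n_sites
    picks = rng.integers(0, 2, size=(n_ind, S))
    rows = 2 * np.arange(n_ind)[:, None] + picks
    haploid = matrix.alleles[rows, np.arange(S)[None, :]].astype(np.int8)
    cell_missing = locus.mask[:, matrix.positions]
    haploid[cell_missing] = MISSING

    assay = locus.assayable_sites(min_called)
    n_assayable = {k: int(v.sum()) for k, v in assay.items()}
    return HaplotypeMatrix(
        alleles=haploid,
        positions=matrix.positions,
        length=matrix.length,
        n_per_species=matrix.n_per_species,
        haploid=True,
        n_assayable=n_assayable,
        min_called=min_called,
    )


def simulate_dataset(
    model: DemographicModel,
    locus_set: LocusSet,
    rng: np.random.Generator,
    min_called: int = 7,
    engines: Optional[Dict[int, LocusEngine]] = None,
    keep_raw: bool = False,
):
    """Simulate, mask and haploidize every locus of a locus set.

    With ``keep_raw`` the pre-haploidization (two-lineages-per-individual)
    matrices are returned alongside, for writing diploid genotype files.
    """
    draw = model.draw
    if draw is None:
        raise ValueError("model carries no parameter draw")
    rates = DatasetRates(
        mean_mu=draw.values["mu"],
        mean_r=draw.values["r"],
        alpha=draw.values["alpha"],
    )
    if engines is None:
        engines = {}
    loci = []
    raw_loci = []
    for locus in locus_set:
        engine = engines.get(locus.length)
        if engine is None or engine.model is not model:
            engine = LocusEngine(model, locus.length, locus_set.n_per_species)
            engines[locus.length] = engine
        mu_locus, r_locus = draw_locus_rates(rates, locus, rng)
        raw = simulate_locus(
            model,
            locus,
            mu_locus,
            r_locus,
            rng,
            n_per_species=locus_set.n_per_species,
            engine=engine,
        )
        if keep_raw:
            raw_loci.append(raw)
        loci.append(apply_mask_and_haploidize(raw, locus, rng, min_called))
    dataset = SimulatedDataset(model.name, draw, loci)
    if keep_raw:
        return dataset, raw_loci
    return dataset


def _row_rng(root_seed: int, model_index: int, row: int, attempt: int = 0):
    ss = np.random.SeedSequence(root_seed, spawn_key=(model_index, row, attempt))
    return np.random.default_rng(ss), int(ss.generate_state(1, np.uint32)[0])


def simulate_reference_table(
    model_names: Sequence[str] | str,
    locus_set: LocusSet,
    n_sims: int,
    root_seed: int,
    scaling: ScalingConvention = ScalingConvention(),
    priors_map: Optional[Dict[str, Sequence]] = None,
    min_called: int = 7,
    max_attempts: int = 10,
    checkpoint_path: Optional[str] = None,
    checkpoint_every: int = 1000,
):
    """Build a reference table of (model, parameters, statistics) rows.

    Row ``i`` of model ``j`` is reproducible from ``(root_seed, j, i)``
    alone via counter-based seed splitting, so a table can be produced in
    any row order (or in parallel) with identical content.  A failed row is
    logged and redrawn with a fresh sub-seed, never silently dropped.

    With ``checkpoint_path``, completed rows are appended to a TSV every
    ``checkpoint_every`` rows and an interrupted run resumes from the rows
    already on disk (identical content, by the per-row seeding).
    """
    import json as _json
    from pathlib import Path as _Path

    from .abc_glm import ReferenceTable
    from .sumstats import STAT_NAMES, summarize_dataset

    if isinstance(model_names, str):
        model_names = [model_names]
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")

    records = []
    done: Dict[str, int] = {}
    ckpt = _Path(checkpoint_path) if checkpoint_path else None
    if ckpt is not None and ckpt.exists():
        prev = pd.read_csv(ckpt, sep="\t", float_precision="round_trip")
        records = prev.to_dict("records")
        done = prev["model"].value_counts().to_dict()
        logger.info("resuming from %s: %d rows", ckpt, len(records))
    last_flush = len(records)

    def _flush():
        nonlocal last_flush
        if ckpt is not None and len(records) > last_flush:
            pd.DataFrame.from_records(records).to_csv(
                ckpt, sep="\t", index=False, float_format="%.17g"
            )
            last_flush = len(records)

    failures = 0
    param_names_union: List[str] = []
    for model_index, model_name in enumerate(model_names):
        priors = (
            priors_map[model_name]
            if priors_map and model_name in priors_map
            else default_priors(model_name)
        )
        for p in priors:
            if p.name not in param_names_union:
                param_names_union.append(p.name)
        engines: Dict[int, LocusEngine] = {}
        for row in range(done.get(model_name, 0), n_sims):
            for attempt in range(max_attempts):
                rng, row_seed = _row_rng(root_seed, model_index, row, attempt)
                try:
                    draw = draw_model_parameters(
                        model_name, rng, scaling, priors=priors
                    )
                    model = build_model(model_name, draw, scaling)
                    # engines are keyed per length but bound to one model
                    # object; rebind for the fresh draw
                    engines = {
                        L: LocusEngine(model, L, locus_set.n_per_species)
                        for L in {loc.length for loc in locus_set}
                    }
                    dataset = simulate_dataset(
                        model, locus_set, rng, min_called, engines
                    )
                    stats = summarize_dataset(dataset)
                    rec = {"model": model_name, "seed": row_seed}
                    rec.update(draw.values)
                    rec.update(zip(STAT_NAMES, stats.values))
                    records.append(rec)
                    if len(records) - last_flush >= checkpoint_every:
                        _flush()
                    break
                except Exception:
                    failures += 1
                    logger.exception(
                        "row %d of model %s failed (attempt %d); redrawing",
                        row,
                        model_name,
                        attempt,
                    )
            else:
                raise RuntimeError(
                    f"row {row} of model {model_name} failed {max_attempts} times"
                )
    _flush()
    df = pd.DataFrame.from_records(records)
    priors_map_full = {
        name: (
            priors_map[name]
            if priors_map and name in priors_map
            else default_priors(name)
        )
        for name in model_names
    }
    return ReferenceTable(
        df=df,
        param_names=param_names_union,
        stat_names=list(STAT_NAMES),
        priors=priors_map_full,
        scaling=scaling,
        locus_set_hash=locus_set.content_hash,
        root_seed=root_seed,
        n_failures=failures,
    )
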