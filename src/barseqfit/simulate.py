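"""Synthetic Bar-seq experiments with known ground truth.

Emulates a pooled haploid deletion library (~3000 mutants, two independent
20-nt barcodes per strain) competitively grown for ~5 generations with or
without a toxicant, then sequenced as indexed single-end reads.  Everything
the analysis pipeline consumes can be generated here: barcode catalog,
indexed FASTQ reads, OD600 dose-response curves, and GMT gene-set
annotations — each parameterized and seeded, with the planted per-mutant
fitness recorded in a truth table for parameter-recovery tests.

Model: mutant i with relative doubling rate g_i starting from abundance
a_i0 reaches expected pool share proportional to ``a_i0 * 2**(g_i * d)``
after d pool doublings; under treatment g_i is scaled by the planted
treatment fitness f_i in [0, 1].  Observed counts are a multinomial draw of
the sequencing depth over those shares; substitution errors are applied
i.i.d. per base when reads are written.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import (
    DEFAULT_READ_LENGTH,
    BarcodeCatalog,
    ReadLayout,
    validate_sample_sheet,
)

__all__ = [
    "LibraryDesign",
    "FitnessModel",
    "SimulationConfig",
    "generate_library",
    "expected_proportions",
    "simulate_counts",
    "simulate_experiment",
    "make_sample_sheet",
    "write_reads",
    "simulate_growth_curves",
    "generate_annotations",
    "lognormal_abundance",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default planted treatment fitness per sensitivity class: fraction of
#: wild-type doublings achieved under treatment.  Expected GI = 1 - f, so
#: these span the low/medium/high expressivity range (GI 0.1 / 0.4 / 1.0).
CLASS_FITNESS = {"none": 1.0, "low": 0.9, "medium": 0.6, "high": 0.0}


@dataclass(frozen=True)
class LibraryDesign:
    """Barcoded deletion-library design: mutant ids plus up/dn barcodes.

    Barcodes are unique within a tag class with pairwise Hamming distance
    >= 3, so one-mismatch matching is provably unambiguous.
    """

    mutants: tuple[str, ...]
    uptag: tuple[str, ...]
    dntag: tuple[str, ...]
    layout: ReadLayout = ReadLayout()

    def __post_init__(self) -> None:
        n = len(self.mutants)
        if not (n == len(self.uptag) == len(self.dntag)):
            raise ValueError("mutants/uptag/dntag lengths differ")

    @property
    def n_mutants(self) -> int:
        return len(self.mutants)

    def catalog(self) -> BarcodeCatalog:
        return BarcodeCatalog(
            pd.DataFrame(
                {"uptag_seq": self.uptag, "dntag_seq": self.dntag},
                index=pd.Index(self.mutants, name="mutant_id"),
            )
        )


@dataclass
class FitnessModel:
    """Latent per-mutant fitness: the quantity the GI score estimates.

    baseline_rate
        Relative doubling rate under control (1.0 = wild-type-like).
    treatment_fitness
        f_i in [0, 1]: fraction of its own baseline doublings a mutant
        achieves under treatment; 1 for insensitive mutants.
    class_labels
        Planted sensitivity class per mutant (none/low/medium/high).
    initial_abundance
        Pool composition at t0 (default: equal).
    """

    baseline_rate: np.ndarray
    treatment_fitness: np.ndarray
    class_labels: np.ndarray
    initial_abundance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline_rate = np.asarray(self.baseline_rate, dtype=float)
        self.treatment_fitness = np.asarray(self.treatment_fitness, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.treatment_fitness.min() < 0 or self.treatment_fitness.max() > 1:
            raise ValueError("treatment_fitness must lie in [0, 1]")
        none_mask = self.class_labels == "none"
        if not np.allclose(self.treatment_fitness[none_mask], 1.0):
            raise ValueError("class 'none' requires treatment_fitness == 1")
        if self.initial_abundance is not None:
            self.initial_abundance = np.asarray(self.initial_abundance, dtype=float)
            if (self.initial_abundance < 0).any():
                raise ValueError("initial_abundance must be non-negative")

    @classmethod
    def neutral(cls, n: int) -> "FitnessModel":
        return cls(np.ones(n), np.ones(n), np.array(["none"] * n, dtype=object))

    @classmethod
    def with_planted_classes(
        cls,
        n: int,
        n_low: int = 0,
        n_medium: int = 0,
        n_high: int = 0,
        class_fitness: Mapping[str, float] = CLASS_FITNESS,
        seed: int | None = None,
    ) -> "FitnessModel":
        """Plant sensitivity classes at random positions in the pool."""
        if n_low + n_medium + n_high > n:
            raise ValueError("more planted mutants than pool size")
        labels = np.array(["none"] * n, dtype=object)
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n, size=n_low + n_medium + n_high, replace=False)
        labels[chosen[:n_low]] = "low"
        labels[chosen[n_low : n_low + n_medium]] = "medium"
        labels[chosen[n_low + n_medium :]] = "high"
        f = np.array([class_fitness[c] for c in labels], dtype=float)
        return cls(np.ones(n), f, labels)

    def truth_table(self, mutants: Sequence[str]) -> pd.DataFrame:
        """Per-mutant ground truth: f, expected GI (= 1 - f at baseline 1), class."""
        return pd.DataFrame(
            {
                "treatment_fitness": self.treatment_fitness,
                "expected_gi": self.baseline_rate * (1.0 - self.treatment_fitness),
                "class_label": self.class_labels,
            },
            index=pd.Index(mutants, name="mutant_id"),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level simulation parameters.

    doublings: generations of competitive pool growth (a typical screen
    uses ~5).  reads_per_sample: sequencing depth per sequencing
    unit.  error_rate: per-base substitution probability, at most 0.1.
    A fixed seed makes every downstream artifact byte-identical.
    """

    n_mutants: int = 3000
    doublings: float = 5.0
    reads_per_sample: int = 1_000_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doublings <= 0:
            raise ValueError("doublings must be > 0")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")


def lognormal_abundance(n: int, sigma: float, seed: int | None = None) -> np.ndarray:
    """Log-normally spread initial abundances modelling uneven pooling."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, sigma, size=n))


# ---------------------------------------------------------------------------
# library generation


def generate_library(
    n_mutants: int,
    barcode_length: int = 20,
    seed: int = 0,
    layout: ReadLayout | None = None,
    max_attempts_per_barcode: int = 200,
) -> LibraryDesign:
    """Generate a barcoded library with min-Hamming-distance-3 barcode sets.

    Barcodes are rejection-sampled uniformly over {A,C,G,T}^L; a candidate
    is accepted only if it is at distance >= 3 from every accepted barcode
    of the same tag class.  Raises if the code cannot be completed within
    ``max_attempts_per_barcode`` draws per barcode (e.g. the length is too
    short to support a distance-3 code of the requested size).
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    if barcode_length < 3 and n_mutants > 1:
        raise ValueError(
            f"no distance-3 barcode code of size {n_mutants} exists at length {barcode_length}"
        )
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = ReadLayout(barcode_length=barcode_length)

    def sample_code() -> np.ndarray:
        accepted = np.empty((n_mutants, barcode_length), dtype=np.uint8)
        count = 0
        budget = max_attempts_per_barcode * n_mutants
        while count < n_mutants:
            if budget <= 0:
                raise RuntimeError(
                    f"could not find {n_mutants} barcodes of length {barcode_length} "
                    "with pairwise Hamming distance >= 3"
                )
            budget -= 1
            cand = _BASES[rng.integers(0, 4, size=barcode_length)]
            if count and int((accepted[:count] != cand).sum(axis=1).min()) < 3:
                continue
            accepted[count] = cand
            count += 1
        return accepted

    up = sample_code()
    dn = sample_code()
    width = max(4, len(str(n_mutants)))
    mutants = tuple(f"mut{i + 1:0{width}d}" for i in range(n_mutants))
    return LibraryDesign(
        mutants=mutants,
        uptag=tuple(row.tobytes().decode() for row in up),
        dntag=tuple(row.tobytes().decode() for row in dn),
        layout=layout,
    )


# ---------------------------------------------------------------------------
# pool growth and sequencing counts


def expected_proportions(
    fitness: FitnessModel,
    doublings: float,
    condition: str,
) -> np.ndarray:
    """Expected pool shares after competitive growth (infinite-depth limit)."""
    if condition not in ("control", "treatment"):
        raise ValueError("condition must be 'control' or 'treatment'")
    g = fitness.baseline_rate.copy()
    if condition == "treatment":
        g = g * fitness.treatment_fitness
    a0 = (
        fitness.initial_abundance
        if fitness.initial_abundance is not None
        else np.ones_like(g)
    )
    if not (a0 > 0).any():
        raise ValueError("total pool abundance is zero")
    # Work in log2 space: shares are invariant to the pool-wide scale.
    log_abund = np.log2(np.where(a0 > 0, a0, np.nan)) + g * doublings
    abund = np.where(a0 > 0, np.exp2(log_abund - np.nanmax(log_abund)), 0.0)
    total = abund.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("total pool abundance is zero")
    return abund / total


def simulate_counts(
    design: LibraryDesign,
    fitness: FitnessModel,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Multinomial read counts for one sequencing unit of one condition."""
    p = expected_proportions(fitness, config.doublings, condition)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draw = rng.multinomial(config.reads_per_sample, p)
    return pd.Series(draw, index=pd.Index(design.mutants, name="mutant_id"), name=condition)


def simulate_experiment(
    design: LibraryDesign,
    fitness_by_condition: Mapping[str, FitnessModel],
    config: SimulationConfig,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate counts for every sequencing unit in a sample sheet.

    ``fitness_by_condition`` maps each non-control condition name in the
    sheet to the fitness model acting under it; condition ``control`` uses
    baseline rates.  Each unit gets an independent multinomial draw from a
    seed stream derived from ``config.seed`` and the row position, so the
    table is reproducible irrespective of how units are grouped in files.
    """
    sheet = validate_sample_sheet(sample_sheet)
    columns = {}
    for pos, row in enumerate(sheet.itertuples(index=False)):
        cond = row.condition
        if cond == "control":
            model = next(iter(fitness_by_condition.values()))
            sim_cond = "control"
        else:
            if cond not in fitness_by_condition:
                raise KeyError(f"no fitness model for condition {cond!r}")
            model = fitness_by_condition[cond]
            sim_cond = "treatment"
        rng = np.random.default_rng([config.seed, 101, pos])
        columns[row.sample_id] = simulate_counts(design, model, config, sim_cond, rng)
    return pd.DataFrame(columns)


def make_sample_sheet(conditions: Sequence[str], n_batches: int = 1) -> pd.DataFrame:
    """Sample sheet for a simulated experiment: up+dn units per condition/batch.

    Each batch becomes one FASTQ file; within a file every condition
    contributes an uptag and a dntag sequencing unit with distinct 4-nt
    indices assigned deterministically.
    """
    if "control" not in conditions:
        raise ValueError("conditions must include 'control'")
    from itertools import product

    index_pool = ["".join(p) for p in product("ACGT", repeat=4)]
    rows = []
    for batch in range(1, n_batches + 1):
        pool = iter(index_pool)
        for cond in conditions:
            for tag in ("up", "dn"):
                rows.append(
                    {
                        "sample_id": f"{cond}_b{batch}_{tag}",
                        "index_seq": next(pool),
                        "tag_class": tag,
                        "condition": cond,
                        "batch": str(batch),
                        "fastq": f"batch{batch}.fastq",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read writing


def _apply_substitutions(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate == 0.0:
        return reads
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    codes = lut[reads]
    mask = rng.random(reads.shape) < error_rate
    shift = rng.integers(1, 4, size=reads.shape)
    codes = np.where(mask, (codes + shift) % 4, codes)
    return _BASES[codes]


def write_reads(
    counts: pd.DataFrame,
    design: LibraryDesign,
    sample_sheet: pd.DataFrame,
    config: SimulationConfig,
    out_dir: str | Path,
    gzip_output: bool | None = None,
) -> dict:
    """Write one FASTQ read per counted barcode occurrence, plus a manifest.

    Reads are structured ``index + spacer + barcode`` padded with 'A' to the
    layout read length; substitution errors are applied i.i.d. per base at
    ``config.error_rate``.  Files follow the sample sheet's ``fastq`` column
    (gzip if the name ends in .gz or ``gzip_output`` is set).  The manifest
    records the seed, layout and per-file read counts.
    """
    sheet = validate_sample_sheet(sample_sheet)
    missing = set(sheet["sample_id"]) - set(counts.columns)
    if missing:
        raise ValueError(f"counts lack columns for samples: {sorted(missing)}")
    if list(counts.index) != list(design.mutants):
        raise ValueError("counts row index does not match design mutants")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = design.layout
    pad_byte = ord("A")
    tag_arrays = {
        "up": np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in design.uptag]),
        "dn": np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in design.dntag]),
    }
    manifest: dict = {
        "generator": "barseqfit.simulate.write_reads",
        "seed": config.seed,
        "error_rate": config.error_rate,
        "doublings": config.doublings,
        "layout": {
            "spacer": layout.spacer,
            "barcode_length": layout.barcode_length,
            "read_length": layout.read_length,
        },
        "files": {},
    }
    sheet = sheet.reset_index(drop=True)
    for fname, grp in sheet.groupby("fastq", sort=False):
        use_gzip = gzip_output if gzip_output is not None else str(fname).endswith(".gz")
        path = out_dir / str(fname)
        opener = gzip.open if use_gzip else open
        n_file_reads = 0
        with opener(path, "wt") as handle:
            for pos, row in grp.iterrows():
                rng = np.random.default_rng([config.seed, 202, int(pos)])
                col = counts[row.sample_id].to_numpy()
                n_reads = int(col.sum())
                if n_reads == 0:
                    continue
                mutant_idx = np.repeat(np.arange(len(col)), col)
                prefix = np.frombuffer(
                    (row.index_seq + layout.spacer).encode(), dtype=np.uint8
                )
                reads = np.full((n_reads, layout.read_length), pad_byte, dtype=np.uint8)
                reads[:, : prefix.size] = prefix
                bstart = prefix.size
                reads[:, bstart : bstart + layout.barcode_length] = tag_arrays[row.tag_class][mutant_idx]
                reads = _apply_substitutions(reads, config.error_rate, rng)
                qual = "I" * layout.read_length
                chunks = []
                for j in range(n_reads):
                    chunks.append(
                        f"@{row.sample_id}.{j}\n{reads[j].tobytes().decode()}\n+\n{qual}\n"
                    )
                    if len(chunks) == 10_000:
                        handle.write("".join(chunks))
                        chunks = []
                handle.write("".join(chunks))
                n_file_reads += n_reads
        manifest["files"][str(fname)] = {
            "n_reads": n_file_reads,
            "samples": grp["sample_id"].tolist(),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# growth curves and annotations


def simulate_growth_curves(
    inhibitions: Mapping[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    control_rate: float = 0.5,
    od0: float = 0.2,
    capacity: float = 1.5,
    hours: float = 16.0,
    interval: float = 0.5,
    technical_repeats: int = 3,
) -> pd.DataFrame:
    """OD600 microculture curves for a ladder of doses.

    Emulates a plate-reader dose-finding assay: mid-log cultures inoculated
    at ``od0`` (~0.2 OD600) grow exponentially at
    ``control_rate * (1 - inhibition)`` doublings/hr until they saturate at
    ``capacity`` (a logistic-style plateau), read every ``interval`` hours
    over ``hours``.  Gaussian read noise of sd ``noise_sd`` is applied per
    technical repeat and the reported value is the mean of
    ``technical_repeats`` repeats, as such assays conventionally record.
    Returns a time-indexed frame with one column per dose label.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if technical_repeats < 1:
        raise ValueError("technical_repeats must be >= 1")
    for dose, inh in inhibitions.items():
        if not (0.0 <= inh <= 1.0):
            raise ValueError(f"inhibition for dose {dose} outside [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, hours + 1e-9, interval)
    data = {}
    for dose, inh in inhibitions.items():
        rate = control_rate * (1.0 - inh)
        od = np.minimum(od0 * np.exp2(rate * t), capacity)
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=(technical_repeats, od.size)).mean(axis=0)
        data[str(dose)] = np.maximum(od, 1e-6)
    return pd.DataFrame(data, index=pd.Index(t, name="time_hr"))


def generate_annotations(
    universe: Sequence[str],
    hit_list: Sequence[str],
    planted_terms: Mapping[str, tuple[int, int]],
    seed: int = 0,
):
    """Gene-set collection with planted overlaps against a hit list.

    ``planted_terms`` maps term name -> (K, k): the term has exactly K
    members of which exactly k are drawn from ``hit_list`` and the rest
    uniformly from the remainder of the universe, so fold enrichment and
    hypergeometric p-values are known by construction.
    """
    from .enrich import GeneSetCollection

    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    hits = [g for g in hit_list if g in uset]
    non_hits = [g for g in universe if g not in set(hit_list)]
    rng = np.random.default_rng(seed)
    sets = {}
    for name, (K, k) in planted_terms.items():
        if k > K:
            raise ValueError(f"{name}: overlap k={k} exceeds term size K={K}")
        if K > len(universe):
            raise ValueError(f"{name}: term size K={K} exceeds universe size {len(universe)}")
        if k > len(hits):
            raise ValueError(f"{name}: overlap k={k} exceeds hit list size {len(hits)}")
        if K - k > len(non_hits):
            raise ValueError(f"{name}: K - k = {K - k} exceeds non-hit universe")
        members = list(rng.choice(hits, size=k, replace=False)) + list(
            rng.choice(non_hits, size=K - k, replace=False)
        )
        sets[name] = set(members)
    return GeneSetCollection(sets=sets, universe=uset)
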