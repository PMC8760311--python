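"""Generators with known ground truth for every pipeline input.

The generators emulate the study conditions of a pooled insertion-mutant
predation screen and a natural-isolate competition experiment:

- a mutant pool (~10⁴ insertions) with heavy-tailed (log-normal) starting
  abundances;
- per-prey fitness effects drawn from a mixture of neutral, prey-specific,
  positively pleiotropic and antagonistically pleiotropic classes;
- serial passage: deterministic exponential growth within a round (~10
  generations), then a multinomial bottleneck of 2.5×10⁵ cells, then
  multinomial sequencing sampling — stochasticity enters only at the
  bottleneck and the sequencer, which keeps expectations analytic;
- junction-read FASTQ assembly for the read-processing round trip;
- a spike-in design (four groups of eight mutants mixed over a 1000-fold
  abundance range);
- strain × bacterium competition tables with block structure; and
- a two-predator / two-prey mixture toy model for coexistence.

All randomness flows from one seed through named substreams, so adding
samples never perturbs existing ones and identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import CountTable, ReadLayout
from .tag_reference import TagTable

DEFAULT_PREY = ("Ka", "Kp", "Bs", "Ml")

#: Vector-specific indices marking the two junction sides of a read.
UPSTREAM_INDEX = "AACC"
DOWNSTREAM_INDEX = "GGTT"

EFFECT_CLASSES = (
    "neutral",
    "conditional_deleterious",
    "conditional_advantaged",
    "positive",
    "antagonistic",
)


def _substream(seed: int, *names) -> np.random.Generator:
    """Deterministic, order-independent child generator for a named stream."""
    key = ":".join(str(n) for n in names)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(key.encode()),))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a serial-passage selection.

    Defaults mirror the study conditions: 2.5×10⁵-cell bottlenecks, ~10
    generations of growth per round, 10 rounds per prey except K. aerogenes
    (20), duplicate selections per prey, triplicate sequencing of the start
    library.  Effect sizes are per-generation relative fitnesses; the default
    ±0.04 log₂ units per generation is 0.4 log₂ units per round, i.e. a
    ±4 log₂-unit expected fold change over a 10-round selection.  Class
    proportions loosely echo the empirical pattern (most mutations neutral,
    most effects prey-specific, antagonistic pleiotropy rare); they are
    generator knobs, not claims about any particular genome.
    """

    seed: int = 0
    n_mutants: int = 10_000
    prey: tuple[str, ...] = DEFAULT_PREY
    abundance_sigma: float = 1.0  # log-normal sd of starting abundances
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "neutral": 0.80,
            "conditional_deleterious": 0.08,
            "conditional_advantaged": 0.04,
            "positive": 0.05,
            "antagonistic": 0.03,
        }
    )
    log2_effect_per_generation: float = 0.04
    positive_deleterious_fraction: float = 0.9  # most positive pleiotropy is deleterious
    bottleneck_cells: int = 250_000
    generations_per_round: int = 10
    rounds: Mapping[str, int] = field(
        default_factory=lambda: {"Ka": 20, "Kp": 10, "Bs": 10, "Ml": 10}
    )
    reads_per_sample: int = 3_000_000
    n_replicates: int = 2
    n_start_replicates: int = 3
    sequence_every_round: bool = True

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for prey in self.prey:
            if self.rounds.get(prey, 10) < 1:
                raise ValueError("rounds must be ≥ 1")


@dataclass
class TruthTable:
    """Ground truth of a simulated selection.

    ``classes`` maps each mutant to its effect class; ``fitness`` holds the
    per-generation relative fitness w per mutant × prey; ``trajectories``
    holds the post-bottleneck frequency trajectory per (prey, replicate) as a
    (rounds+1, n_mutants) array whose rows each sum to 1.
    """

    classes: pd.Series
    fitness: pd.DataFrame
    start_frequencies: pd.Series
    trajectories: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)


def simulate_toy_genome(
    length: int = 5000, seed: int = 0, gc: float = 0.25, chrom_id: str = "chr1"
) -> tuple[dict[str, str], dict]:
    """Random AT-rich genome with naturally embedded GATC/CATG sites.

    Returns the genome mapping and a report of restriction-site density
    (observed counts of both recognition sequences).
    """
    if length < 500:
        raise ValueError("length must be ≥ 500")
    rng = _substream(seed, "toy_genome", chrom_id)
    p_gc = gc / 2
    bases = rng.choice(
        np.array(list("ACGT")), size=length, p=[0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]
    )
    seq = "".join(bases)
    info = {
        "length": length,
        "n_GATC": seq.count("GATC"),
        "n_CATG": seq.count("CATG"),
    }
    return {chrom_id: seq}, info


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _draw_fitness(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    n, prey = config.n_mutants, list(config.prey)
    classes = rng.choice(
        EFFECT_CLASSES,
        size=n,
        p=[config.class_proportions[c] for c in EFFECT_CLASSES],
    )
    w_adv = 2.0**config.log2_effect_per_generation
    w_del = 2.0**-config.log2_effect_per_generation
    w = np.ones((n, len(prey)))
    for i, cls in enumerate(classes):
        if cls == "neutral":
            continue
        if cls == "conditional_deleterious":
            w[i, rng.integers(len(prey))] = w_del
        elif cls == "conditional_advantaged":
            w[i, rng.integers(len(prey))] = w_adv
        elif cls == "positive":
            # degenerates to a single-prey effect when only one prey is simulated
            k = int(rng.integers(2, len(prey) + 1)) if len(prey) >= 2 else 1
            cols = rng.choice(len(prey), size=k, replace=False)
            value = w_del if rng.random() < config.positive_deleterious_fraction else w_adv
            w[i, cols] = value
        elif cls == "antagonistic":
            if len(prey) >= 2:
                cols = rng.choice(len(prey), size=2, replace=False)
                w[i, cols[0]] = w_adv
                w[i, cols[1]] = w_del
            else:
                w[i, 0] = w_del
    mutants = pd.Index([f"mut{i:05d}" for i in range(n)], name="mutant")
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    start = weights / weights.sum()
    return TruthTable(
        classes=pd.Series(classes, index=mutants, name="class"),
        fitness=pd.DataFrame(w, index=mutants, columns=prey),
        start_frequencies=pd.Series(start, index=mutants, name="start_freq"),
    )


def _grow(freq: np.ndarray, w: np.ndarray, generations: int) -> np.ndarray:
    """Deterministic per-generation frequency update f ∝ f·wᴳ."""
    grown = freq * w**generations
    return grown / grown.sum()


def simulate_selection(
    config: SimulationConfig,
) -> tuple[CountTable, TruthTable]:
    """Simulate the full serial-passage selection and its sequencing.

    Each replicate starts from an independent bottleneck of the shared start
    pool.  Per round: deterministic growth for ``generations_per_round``
    generations, a multinomial bottleneck of ``bottleneck_cells``, and (when
    sampled) a multinomial sequencing draw of ``reads_per_sample`` reads.

    Returns the raw count table (start replicates plus per-round endpoint
    samples; metadata columns ``role``, ``prey``, ``replicate``, ``round``)
    and the :class:`TruthTable`.
    """
    truth = _draw_fitness(config, _substream(config.seed, "fitness"))
    mutants = truth.fitness.index
    start = truth.start_frequencies.to_numpy()

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    for r in range(1, config.n_start_replicates + 1):
        rng = _substream(config.seed, "start_seq", r)
        name = f"start_rep{r}"
        columns[name] = rng.multinomial(config.reads_per_sample, start)
        meta_rows.append({"sample": name, "role": "start", "prey": "", "replicate": r, "round": 0})

    for prey_i, prey in enumerate(config.prey):
        w = truth.fitness[prey].to_numpy()
        n_rounds = config.rounds.get(prey, 10)
        for rep in range(1, config.n_replicates + 1):
            rng = _substream(config.seed, "selection", prey, rep)
            freq = rng.multinomial(config.bottleneck_cells, start) / config.bottleneck_cells
            trajectory = [freq]
            for rnd in range(1, n_rounds + 1):
                freq = _grow(freq, w, config.generations_per_round)
                cells = rng.multinomial(config.bottleneck_cells, freq)
                freq = cells / config.bottleneck_cells
                trajectory.append(freq)
                is_end = rnd == n_rounds
                if is_end or config.sequence_every_round:
                    name = f"{prey}_rep{rep}_round{rnd}"
                    columns[name] = rng.multinomial(config.reads_per_sample, freq)
                    meta_rows.append(
                        {
                            "sample": name,
                            "role": "end" if is_end else "intermediate",
                            "prey": prey,
                            "replicate": rep,
                            "round": rnd,
                        }
                    )
            truth.trajectories[(prey, rep)] = np.vstack(trajectory)

    raw = pd.DataFrame(columns, index=mutants)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountTable(raw=raw, samples=samples), truth


def expected_log2_fold_change(
    w: float, generations: int, rounds: int, log_base: float = 2.0
) -> float:
    """Deterministic expectation of a rare mutant's log fold change.

    In the rare-mutant limit among an (essentially) neutral pool, frequency
    changes by wᴳ per round, so the expected log₂ fold change after R rounds
    is R·G·log₂(w).
    """
    return rounds * generations * np.log(w) / np.log(log_base)


def simulate_reads(
    pool_counts: Mapping[str, pd.Series],
    table: TagTable,
    layout: ReadLayout | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Assemble junction reads for each sample from per-insertion read counts.

    Each insertion's reads are split evenly in expectation between its
    upstream tag (carrying :data:`UPSTREAM_INDEX`) and its downstream tag
    (:data:`DOWNSTREAM_INDEX`).  At ``error_rate`` 0 the downstream count
    table reproduces the input exactly; positive rates introduce uniform
    substitution errors across the whole read.

    Returns ``{sample: [(read id, sequence), ...]}``; use
    :func:`write_fastq_reads` to serialise.
    """
    layout = layout or ReadLayout()
    side_tags: dict[str, dict[str, str]] = {}
    for tag in table.entries:
        insertion = f"{tag.site.chromosome}:{tag.site.position}"
        side_tags.setdefault(insertion, {})[tag.side] = tag.sequence

    alphabet = np.array(list("ACGT"))
    out: dict[str, list[tuple[str, str]]] = {}
    for sample, counts in pool_counts.items():
        rng = _substream(seed, "reads", sample)
        reads: list[tuple[str, str]] = []
        for insertion, n_reads in counts.items():
            n_reads = int(n_reads)
            if n_reads == 0:
                continue
            if insertion not in side_tags:
                raise ValueError(f"no tags known for insertion {insertion}")
            tags = side_tags[insertion]
            n_up = int(rng.binomial(n_reads, 0.5)) if len(tags) == 2 else (
                n_reads if "upstream" in tags else 0
            )
            for side, index, n in (
                ("upstream", UPSTREAM_INDEX, n_up),
                ("downstream", DOWNSTREAM_INDEX, n_reads - n_up),
            ):
                if n == 0 or side not in tags:
                    continue
                template = (
                    layout.adapter_sequences[0]
                    + layout.vector_sequence
                    + index[: layout.index_length]
                    + tags[side]
                )
                for k in range(n):
                    seq = template
                    if error_rate > 0:
                        arr = np.array(list(seq))
                        hits = rng.random(len(arr)) < error_rate
                        if hits.any():
                            arr[hits] = alphabet[rng.integers(0, 4, size=hits.sum())]
                            seq = "".join(arr)
                    reads.append((f"{sample}:{insertion}:{side}:{k}", seq))
        out[sample] = reads
    return out


def write_fastq_reads(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_spikein(
    n_groups: int = 4,
    mutants_per_group: int = 8,
    cell_numbers: Sequence[float] = (1e5, 1e6, 1e7, 1e8),
    reads_per_sample: int = 1_000_000,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame]:
    """Spike-in design probing the quantitative dynamic range.

    Mutants are split into groups (A, B, …) of equal size; pool ``P{i}``
    spikes group g at ``cell_numbers`` rotated by i, so every group visits
    every abundance across the pools.  Sequencing is a multinomial draw per
    pool.  Returns the raw count table and a truth frame (mutant, group,
    cells per pool).
    """
    if len(cell_numbers) != n_groups:
        raise ValueError("need one cell number per group")
    groups = [chr(ord("A") + g) for g in range(n_groups)]
    mutants = [
        f"{groups[g]}{m+1:02d}" for g in range(n_groups) for m in range(mutants_per_group)
    ]
    group_of = np.repeat(np.arange(n_groups), mutants_per_group)

    columns: dict[str, np.ndarray] = {}
    truth_rows = {"mutant": mutants, "group": [groups[g] for g in group_of]}
    for p in range(n_groups):
        cells = np.array([cell_numbers[(g + p) % n_groups] for g in group_of], float)
        probs = cells / cells.sum()
        rng = _substream(seed, "spikein", p)
        pool = f"P{p+1}"
        columns[pool] = rng.multinomial(reads_per_sample, probs)
        truth_rows[f"cells_{pool}"] = cells
    raw = pd.DataFrame(columns, index=pd.Index(mutants, name="mutant"))
    samples = pd.DataFrame(
        {"role": "pool", "prey": "", "replicate": range(1, n_groups + 1), "round": 0},
        index=pd.Index(columns, name="sample"),
    )
    return CountTable(raw=raw, samples=samples), pd.DataFrame(truth_rows)


def simulate_competition(
    effects: pd.DataFrame,
    n_blocks: int = 2,
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    block_sd: float = 0.02,
    bacterium_block_sd: float = 0.01,
    start_jitter_sd: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Competition observations from a known strain × bacterium effect matrix.

    Start frequencies sit near 0.5; end frequency = start + effect + block
    shift + bacterium-by-block shift + residual noise, clipped to [0, 1] —
    the same structure the mixed model in
    :func:`remiscreen.competition_analysis.estimate_means` assumes.  The
    Gaussian noise model is an explicit stand-in: the real assays publish no
    noise model.
    """
    strains, bacteria = list(effects.index), list(effects.columns)
    rng = _substream(seed, "competition")
    block_shift = rng.normal(0.0, block_sd, size=n_blocks)
    bb_shift = rng.normal(0.0, bacterium_block_sd, size=(len(bacteria), n_blocks))
    rows = []
    for bi, bacterium in enumerate(bacteria):
        for strain in strains:
            for block in range(n_blocks):
                for _ in range(n_replicates):
                    start = np.clip(0.5 + rng.normal(0.0, start_jitter_sd), 0.0, 1.0)
                    end = (
                        start
                        + effects.loc[strain, bacterium]
                        + block_shift[block]
                        + bb_shift[bi, block]
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append(
                        {
                            "strain": strain,
                            "bacterium": bacterium,
                            "block": f"block{block+1}",
                            "start_freq": round(float(start), 6),
                            "end_freq": round(float(np.clip(end, 0.0, 1.0)), 6),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_prey_mixture(
    fitness: pd.DataFrame,
    mixture_grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 21)),
    generations: int = 10,
) -> pd.DataFrame:
    """Two-predator growth on a two-prey mixture (replenished prey supply).

    ``fitness`` is a 2 strains × 2 prey table of per-generation growth
    factors.  At prey-1 fraction x each strain grows by its
    consumption-weighted factor ``x·w₁ + (1−x)·w₂`` per generation from a
    50:50 start.  Returns the end frequency of the first strain across the
    grid; with opposite per-prey advantages the curve crosses 0.5 at an
    interior mixture.
    """
    if fitness.shape != (2, 2):
        raise ValueError("fitness must be 2 strains × 2 prey")
    w = fitness.to_numpy(dtype=float)
    rows = []
    for x in mixture_grid:
        rates = x * w[:, 0] + (1 - x) * w[:, 1]
        biomass = 0.5 * rates**generations
        rows.append({"prey1_fraction": float(x), "end_freq_strain1": float(biomass[0] / biomass.sum())})
    return pd.DataFrame(rows)
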