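"""Synthetic MeDIP-seq-like data: genomes, planted epimutations, window counts.

The generator emulates the statistical structure a window-level differential
methylation analysis consumes: per-sample read counts over non-overlapping
1 kb genomic windows, negative-binomially dispersed around a common baseline,
with multiplicative per-sample library-depth variation and a set of planted
multi-window differentially methylated regions (DMRs) between a "disease" and
a "no disease" group. Everything downstream of read alignment is exercisable
from this module alone; nothing upstream (fragments, reads, enrichment bias)
is modelled.

The count model for window *w*, sample *s* is

    count[w, s] ~ NB(mean = mu * L_s * 2^(±delta · 1[w planted, s diseased]),
                     variance = mean + phi · mean²)

with baseline mean ``mu``, lognormal depth factor ``L_s``, planted log2 effect
``delta`` (sign per region: half the planted regions gain methylation, half
lose it), and dispersion ``phi`` (``phi = 0`` is the Poisson limit).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

_BASES = np.frombuffer(b"ATG", dtype="S1")  # no lone C: CpGs only where planted


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults are the package's reference study conditions: a two-chromosome
    20,000-window (20 Mb) genome, 8 diseased vs 8 non-diseased samples at a
    baseline depth of 50 reads/window, NB dispersion 0.1, 10% lognormal
    library-depth spread, and 20 planted 3-window DMRs with a |log2 FC| of 2.
    """

    n_chromosomes: int = 2
    windows_per_chromosome: int = 10_000
    window_size: int = 1000
    n_disease: int = 8
    n_control: int = 8
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    libsize_factor_sd: float = 0.1
    n_dmrs: int = 20
    dmr_span: int = 3
    effect_log2: float = 2.0
    cpg_rate: float = 2.0  # expected CpG dinucleotides per 100 bp
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "windows_per_chromosome": self.windows_per_chromosome,
            "window_size": self.window_size,
            "n_disease": self.n_disease,
            "n_control": self.n_control,
            "baseline_mean": self.baseline_mean,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        for name, value in {
            "dispersion": self.dispersion,
            "libsize_factor_sd": self.libsize_factor_sd,
            "n_dmrs": self.n_dmrs,
            "dmr_span": self.dmr_span,
            "cpg_rate": self.cpg_rate,
        }.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.n_dmrs > 0 and self.dmr_span <= 0:
            raise ConfigurationError("dmr_span must be > 0 when planting DMRs")


@dataclass
class GenomeModel:
    """Chromosome lengths, the window grid, and per-window CpG counts.

    ``windows`` has columns (chrom, start, end); ``cpg_counts`` aligns with its
    rows. ``sequences`` optionally holds explicit nucleotide sequence per
    chromosome, consistent with the CpG counts (CpG dinucleotides occur only
    at the counted positions, none span a window boundary).
    """

    chrom_lengths: dict[str, int]
    windows: pd.DataFrame
    cpg_counts: np.ndarray
    sequences: dict[str, str] | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class TruthSet:
    """Planted epimutation regions, on the window grid and non-overlapping.

    ``regions`` has columns (chrom, start, end, name, effect_log2, direction)
    where direction is "hyper" (methylation gain in the disease group) or
    "hypo"; ``window_mask``/``window_sign`` align with the genome's windows.
    """

    regions: pd.DataFrame
    window_mask: np.ndarray
    window_sign: np.ndarray


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]


def simulate_genome(
    config: SimulationConfig, store_sequence: bool = False
) -> GenomeModel:
    """Build the synthetic genome and its window grid.

    CpG counts per window are binomial over eligible dinucleotide start
    positions at the configured rate; with ``store_sequence`` an explicit
    sequence is generated whose CpG occurrences match the counts exactly.
    """
    rng = _substreams(config.seed, 3)[0]
    wsize = config.window_size
    length = config.windows_per_chromosome * wsize
    chrom_lengths = {
        f"chr{i + 1}": length for i in range(config.n_chromosomes)
    }

    rows = []
    for chrom, clen in chrom_lengths.items():
        starts = np.arange(0, clen, wsize)
        ends = np.minimum(starts + wsize, clen)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    windows = pd.concat(rows, ignore_index=True)

    # A CpG occupies 2 bp; cap counts so placements cannot collide.
    n_slots = (wsize - 1)  # dinucleotide start positions fully inside a window
    p = min(1.0, config.cpg_rate / 100.0)
    cpg = rng.binomial(n_slots, p, size=len(windows))
    cpg = np.minimum(cpg, wsize // 2)

    sequences = None
    if store_sequence:
        sequences = {}
        offset = 0
        for chrom, clen in chrom_lengths.items():
            n_win = int(np.ceil(clen / wsize))
            seq = rng.choice(_BASES, size=clen)
            for wi in range(n_win):
                k = int(cpg[offset + wi])
                if k == 0:
                    continue
                lo = wi * wsize
                hi = min(lo + wsize, clen) - 1  # CpG must not cross the edge
                # place k non-overlapping CpGs: pick from even offsets
                slots = np.arange(lo, hi, 2)
                k = min(k, len(slots))
                pos = rng.choice(slots, size=k, replace=False)
                seq[pos] = b"C"
                seq[pos + 1] = b"G"
            sequences[chrom] = seq.tobytes().decode()
            offset += n_win

    return GenomeModel(chrom_lengths, windows, cpg, sequences)


def plant_epimutations(genome: GenomeModel, config: SimulationConfig) -> TruthSet:
    """Choose non-overlapping grid-aligned regions to carry the planted effect.

    Half the regions (alternating after a seeded shuffle) are hypermethylated
    in the disease group, half hypomethylated.
    """
    rng = _substreams(config.seed, 3)[1]
    span = config.dmr_span
    n = config.n_dmrs
    windows = genome.windows
    mask = np.zeros(len(windows), dtype=bool)
    sign = np.zeros(len(windows), dtype=np.int8)
    if n == 0:
        return TruthSet(
            pd.DataFrame(
                columns=["chrom", "start", "end", "name", "effect_log2",
                         "direction"]
            ),
            mask,
            sign,
        )

    # candidate start windows per chromosome such that the span stays within
    # one chromosome; sample without replacement, reject overlaps greedily.
    chrom_index = windows.groupby("chrom", sort=False).indices
    candidates = []
    for chrom, idx in chrom_index.items():
        idx = np.asarray(idx)
        if len(idx) >= span:
            candidates.append(idx[: len(idx) - span + 1])
    candidates = np.concatenate(candidates) if candidates else np.array([], int)
    if n * span > genome.n_windows or len(candidates) == 0:
        raise ConfigurationError(
            f"cannot place {n} regions of {span} windows in "
            f"{genome.n_windows} windows"
        )

    order = rng.permutation(candidates)
    chosen: list[int] = []
    occupied = np.zeros(len(windows), dtype=bool)
    for start in order:
        if len(chosen) == n:
            break
        block = slice(start, start + span)
        if occupied[block].any():
            continue
        chosen.append(int(start))
        occupied[block] = True
    if len(chosen) < n:
        raise ConfigurationError(
            f"insufficient genome space: placed {len(chosen)} of {n} regions"
        )
    chosen.sort()

    directions = np.array(["hyper", "hypo"] * ((n + 1) // 2))[:n]
    directions = directions[rng.permutation(n)]

    rows = []
    for i, (start_idx, direction) in enumerate(zip(chosen, directions)):
        sl = slice(start_idx, start_idx + span)
        mask[sl] = True
        s = 1 if direction == "hyper" else -1
        sign[sl] = s
        sub = windows.iloc[sl]
        rows.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].iloc[0]),
                "end": int(sub["end"].iloc[-1]),
                "name": f"epimut_{i + 1}",
                "effect_log2": s * config.effect_log2,
                "direction": direction,
            }
        )
    regions = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(
        drop=True
    )
    return TruthSet(regions, mask, sign)


def simulate_window_counts(
    genome: GenomeModel, truth: TruthSet, config: SimulationConfig
):
    """Draw the window × sample count matrix.

    Returns a :class:`~epidmr.counts.WindowCountMatrix`. Disease samples at
    planted windows have their mean scaled by ``2^(±effect_log2)``; all counts
    are NB with variance ``mean + phi·mean²`` (Poisson when ``phi = 0``).
    """
    from .counts import WindowCountMatrix  # deferred: avoid cycle

    rng = _substreams(config.seed, 3)[2]
    n_d, n_c = config.n_disease, config.n_control
    n_samples = n_d + n_c
    samples = [f"D{i + 1:02d}" for i in range(n_d)] + [
        f"C{i + 1:02d}" for i in range(n_c)
    ]
    groups = np.array(["disease"] * n_d + ["no_disease"] * n_c)

    if config.libsize_factor_sd > 0:
        libfactors = rng.lognormal(0.0, config.libsize_factor_sd, n_samples)
    else:
        libfactors = np.ones(n_samples)

    mean = np.full((genome.n_windows, n_samples), config.baseline_mean)
    effect = np.power(
        2.0, config.effect_log2 * truth.window_sign.astype(float)
    )
    mean[:, :n_d] *= effect[:, None]
    mean *= libfactors[None, :]

    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)

    return WindowCountMatrix(
        windows=genome.windows.copy(),
        counts=counts.astype(np.int64),
        samples=list(samples),
        groups=list(groups),
        library_sizes=counts.sum(axis=0).astype(np.int64),
    )


def simulate_dataset(config: SimulationConfig, store_sequence: bool = False):
    """Convenience: genome + truth + counts in one call."""
    genome = simulate_genome(config, store_sequence=store_sequence)
    truth = plant_epimutations(genome, config)
    matrix = simulate_window_counts(genome, truth, config)
    return genome, truth, matrix


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(**d)
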