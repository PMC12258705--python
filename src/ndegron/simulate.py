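"""Synthetic sorted-library generator.

Emulates a five-codon NNK saturation library at a reporter neo-N-terminus,
sorted by fluorescence into four bins (B1 least stable .. B4 most stable) and
amplicon-sequenced per bin, so that every downstream stage of the pipeline
(demultiplexing, filtering, PSI estimation, comparative analytics, model
training) can be exercised against known ground truth.

The generative model, layer by layer:

* ``EffectModel`` — each motif's *true stability* on the PSI scale [1, 4] is a
  baseline plus additive residue-at-position effects plus optional pairwise
  interaction effects, clamped to [1, 4].  Effects can be flagged as dependent
  on a pathway component (ClpS or LFTR); the corresponding knockout genotype
  suppresses them, mirroring how adaptor loss flattens sequence dependence.
* ``SortModel`` — a cell's latent log-fluorescence is Gaussian around the true
  stability; three ascending thresholds partition the latent axis into the
  four sort bins.  With thresholds at the PSI quartiles and a noise SD
  comparable to the bin width, the expected PSI of the resulting bin
  probabilities is approximately the latent stability itself (the readout is
  calibrated); see docs/methods.md.
* read allocation — by default each sequenced read picks a motif from a
  log-normal abundance distribution and then a bin from that motif's bin
  probabilities ("cell" allocation, the physical sorting process).  A "bin"
  allocation mode with fixed per-bin read depths is also provided.
* reads — each read is the assembled amplicon (upstream flank with a 3-nt bin
  barcode, the 15-nt mutagenized region, a 15-nt anchor, downstream flank)
  with i.i.d. substitution errors.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .amplicon import DEFAULT_BARCODES, DEFAULT_TEMPLATE, AmpliconTemplate, BIN_IDS
from .genetics import (
    AA_SET,
    AA_TO_NNK_CODONS,
    CODON_TO_AA,
    GENOTYPES,
    STOP_CODONS,
    validate_motif,
)

PSI_MIN, PSI_MAX = 1.0, 4.0

EffectKey = tuple[str, int]  # (residue, position 1..5)
PairKey = tuple[EffectKey, EffectKey]


def _check_effect_key(key: EffectKey) -> None:
    residue, position = key
    if residue not in AA_SET:
        raise ValueError(f"unknown residue {residue!r} in effect key")
    if position not in (1, 2, 3, 4, 5):
        raise ValueError(f"position {position} out of range 1..5")


@dataclass
class EffectModel:
    """Ground-truth additive(+interaction) stability model on the PSI scale.

    ``genotype_masks`` maps a genotype to the set of effect keys that are
    *suppressed* in that genotype, e.g. ClpS-dependent destabilization
    vanishing in the ClpS knockout.
    """

    baseline: float = 3.5
    residue_effects: dict[EffectKey, float] = field(default_factory=dict)
    pair_effects: dict[PairKey, float] = field(default_factory=dict)
    genotype_masks: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.residue_effects:
            _check_effect_key(key)
        for a, b in self.pair_effects:
            _check_effect_key(a)
            _check_effect_key(b)
        for genotype in self.genotype_masks:
            if genotype not in GENOTYPES:
                raise ValueError(f"unknown genotype {genotype!r}")

    def masked(self, genotype: str) -> set:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
        return self.genotype_masks.get(genotype, set())


def true_stability(motif: str, model: EffectModel, genotype: str = "WT") -> float:
    """True stability of ``motif`` under ``model`` in ``genotype``, clamped
    to the attainable PSI range [1, 4]."""
    validate_motif(motif)
    masked = model.masked(genotype)
    score = model.baseline
    for position, residue in enumerate(motif, start=1):
        key = (residue, position)
        if key in model.residue_effects and key not in masked:
            score += model.residue_effects[key]
    for pair, effect in model.pair_effects.items():
        if pair in masked:
            continue
        (res_a, pos_a), (res_b, pos_b) = pair
        if motif[pos_a - 1] == res_a and motif[pos_b - 1] == res_b:
            score += effect
    return float(min(PSI_MAX, max(PSI_MIN, score)))


def stability_vector(motifs, model: EffectModel, genotype: str = "WT") -> np.ndarray:
    return np.array([true_stability(m, model, genotype) for m in motifs])


@dataclass
class SortModel:
    """Latent-Gaussian four-bin sorting model.

    ``bin_thresholds`` partition the latent fluorescence axis (expressed on
    the PSI scale) into B1 < t1 < B2 < t2 < B3 < t3 < B4; B4 is the
    highest-fluorescence, most-stable bin.  ``bin_depths`` are the per-bin
    read budgets used by the fixed-depth ("bin") allocation mode; the default
    is the study's WT sorted-cell profile scaled to a 400,000-read total.
    """

    noise_sd: float = 0.8
    bin_thresholds: tuple[float, float, float] = (1.75, 2.5, 3.25)
    bin_depths: tuple[int, int, int, int] = (38114, 45116, 77421, 239349)
    orientation: str = "B4_most_stable"

    def __post_init__(self) -> None:
        t = self.bin_thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("bin thresholds must be strictly ascending")
        if any(d <= 0 for d in self.bin_depths):
            raise ValueError("bin depths must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def total_depth(self) -> int:
        return int(sum(self.bin_depths))


def bin_probabilities(score, sort: SortModel) -> np.ndarray:
    """Probability of a cell with latent stability ``score`` landing in each
    bin B1..B4.  Vectorised over ``score``; rows sum to 1.

    With ``noise_sd == 0`` the mass degenerates onto the bin containing the
    score (a score exactly at a threshold is assigned to the bin above it).
    """
    score = np.asarray(score, dtype=float)
    scalar = score.ndim == 0
    score = np.atleast_1d(score)
    thresholds = np.asarray(sort.bin_thresholds)
    if sort.noise_sd == 0:
        idx = np.searchsorted(thresholds, score, side="right")
        probs = np.zeros((score.size, 4))
        probs[np.arange(score.size), idx] = 1.0
    else:
        z = (thresholds[None, :] - score[:, None]) / sort.noise_sd
        cdf = norm.cdf(z)
        edges = np.concatenate(
            [np.zeros((score.size, 1)), cdf, np.ones((score.size, 1))], axis=1
        )
        probs = np.diff(edges, axis=1)
        probs /= probs.sum(axis=1, keepdims=True)
    return probs[0] if scalar else probs


def expected_psi(bin_probs) -> np.ndarray | float:
    """Expected PSI of a bin-probability vector: sum of p_i * i, i = 1..4."""
    bin_probs = np.asarray(bin_probs, dtype=float)
    return bin_probs @ np.arange(1, 5)


# ---------------------------------------------------------------------------
# library construction


@dataclass
class SimConfig:
    """Configuration for one simulated sort-and-sequence experiment."""

    n_motifs: int | str = 2000
    abundance_dispersion: float = 0.5
    substitution_error_rate: float = 0.001
    seed: int = 0
    total_reads: int = 400_000
    allocation: str = "cell"  # "cell" (default, motif-first) or "bin"
    barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    template: AmpliconTemplate = field(default_factory=lambda: DEFAULT_TEMPLATE)

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_error_rate <= 0.1):
            raise ValueError("substitution_error_rate must be within [0, 0.1]")
        barcodes = list(self.barcodes.values())
        if len(set(barcodes)) != len(barcodes) or any(len(b) != 3 for b in barcodes):
            raise ValueError("barcodes must be distinct 3-nt strings")
        if self.allocation not in ("cell", "bin"):
            raise ValueError("allocation must be 'cell' or 'bin'")


@dataclass
class MotifLibrary:
    """A set of distinct amino-acid motifs with representative NNK DNA and
    relative abundances (log-normal, normalised to sum 1)."""

    motifs: list[str]
    dna: list[str]
    abundance: np.ndarray

    def __len__(self) -> int:
        return len(self.motifs)


def sample_nnk_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Draw ``n_codons`` NNK codons position-wise: positions 1-2 uniform over
    A/C/G/T, position 3 uniform over G/T.  Stop-containing codons (TAG) are
    legal draws and are *not* rejected."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    n = rng.integers(0, 4, size=(n_codons, 2))
    k = rng.integers(0, 2, size=(n_codons, 1))
    bases = np.array(list("ACGT"))
    kbases = np.array(list("GT"))
    codons = np.concatenate([bases[n], kbases[k]], axis=1)
    return "".join(codons.ravel())


def _translate_nnk(dna: str) -> str | None:
    """Translate a 15-nt sequence; None if any codon is a stop."""
    residues = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            return None
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


def build_library(
    rng: np.random.Generator,
    n_motifs: int,
    abundance_dispersion: float = 0.5,
) -> MotifLibrary:
    """Sample ``n_motifs`` distinct amino-acid motifs by drawing NNK 15-mers,
    dropping stop-containing draws, and de-duplicating at the motif level
    (first drawn DNA is kept as the representative)."""
    seen: dict[str, str] = {}
    # NNK redundancy means motif collisions; oversample in batches.
    while len(seen) < n_motifs:
        batch = max(1000, 2 * (n_motifs - len(seen)))
        dna_block = sample_nnk_codons(rng, 5 * batch)
        for j in range(batch):
            dna = dna_block[15 * j : 15 * (j + 1)]
            motif = _translate_nnk(dna)
            if motif is not None and motif not in seen:
                seen[motif] = dna
                if len(seen) == n_motifs:
                    break
    motifs = list(seen)
    abundance = rng.lognormal(mean=0.0, sigma=abundance_dispersion, size=n_motifs)
    abundance /= abundance.sum()
    return MotifLibrary(motifs=motifs, dna=[seen[m] for m in motifs], abundance=abundance)


# ---------------------------------------------------------------------------
# sorting + sequencing


def simulate_bin_counts(
    library: MotifLibrary,
    effects: EffectModel,
    sort: SortModel,
    genotype: str,
    rng: np.random.Generator,
    total_reads: int | None = None,
    allocation: str = "cell",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-motif read counts across the four bins (no sequencing
    errors; the counts level of the generative model).

    Returns ``(counts, truth)``: ``counts`` has columns motif, count_b1..b4;
    ``truth`` has motif, true_stability, expected_psi, abundance.

    allocation="cell": draw each read's motif from the abundance distribution,
    then its bin from the motif's bin probabilities.  allocation="bin": fill
    each bin's fixed depth (``sort.bin_depths``) by a multinomial over motifs
    weighted by abundance times the motif's probability of that bin.
    """
    n = len(library)
    stabilities = stability_vector(library.motifs, effects, genotype)
    probs = bin_probabilities(stabilities, sort)
    counts = np.zeros((n, 4), dtype=np.int64)
    if allocation == "cell":
        total = int(total_reads if total_reads is not None else sort.total_depth)
        per_motif = rng.multinomial(total, library.abundance)
        for m in range(n):
            if per_motif[m]:
                counts[m] = rng.multinomial(per_motif[m], probs[m])
    elif allocation == "bin":
        for i in range(4):
            weights = library.abundance * probs[:, i]
            mass = weights.sum()
            if mass == 0:
                continue
            counts[:, i] = rng.multinomial(sort.bin_depths[i], weights / mass)
    else:
        raise ValueError("allocation must be 'cell' or 'bin'")
    if counts.sum() < n:
        warnings.warn(
            f"{counts.sum()} reads cannot represent all {n} motifs",
            stacklevel=2,
        )
    counts_df = pd.DataFrame(
        counts, columns=[f"count_{b.lower()}" for b in BIN_IDS]
    )
    counts_df.insert(0, "motif", library.motifs)
    truth = pd.DataFrame(
        {
            "motif": library.motifs,
            "true_stability": stabilities,
            "expected_psi": expected_psi(probs),
            "abundance": library.abundance,
        }
    )
    return counts_df, truth


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate_reads(block: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitution errors to a (n_reads, read_len) uint8 array
    of ACGT bytes; a substituted base is uniform over the three others."""
    if rate <= 0:
        return block
    mask = rng.random(block.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return block
    # map byte -> 0..3, shift by 1..3 mod 4, map back
    idx = np.searchsorted(_BASES, block[mask])
    shifted = (idx + rng.integers(1, 4, size=n_err)) % 4
    block = block.copy()
    block[mask] = _BASES[shifted]
    return block


def simulate_sorted_reads(
    config: SimConfig,
    effects: EffectModel,
    sort: SortModel,
    genotype: str,
    outdir: str | Path,
    library: MotifLibrary | None = None,
) -> dict:
    """End-to-end simulation: build (or reuse) a library, sort it, and write
    one FASTQ per bin plus a ground-truth TSV.

    Returns a dict with keys ``fastq`` (bin -> path), ``truth`` (path),
    ``counts`` (the per-motif allocation DataFrame) and ``library``.
    Output is byte-identical for identical ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if library is None:
        if config.n_motifs == "full":
            raise ValueError(
                "full-space simulation must be requested through the CLI guard; "
                "pass an explicit MotifLibrary instead"
            )
        library = build_library(rng, int(config.n_motifs), config.abundance_dispersion)
    counts_df, truth = simulate_bin_counts(
        library,
        effects,
        sort,
        genotype,
        rng,
        total_reads=config.total_reads,
        allocation=config.allocation,
    )
    template = config.template
    counts = counts_df[[f"count_{b.lower()}" for b in BIN_IDS]].to_numpy()
    fastq_paths: dict[str, Path] = {}
    qual_line = "I" * template.read_length
    for i, bin_id in enumerate(BIN_IDS):
        barcode = config.barcodes[bin_id]
        path = outdir / f"{genotype}_{bin_id}.fastq"
        fastq_paths[bin_id] = path
        with open(path, "w") as fh:
            serial = 0
            # assemble clean reads per motif, replicate by count, add errors
            for start in range(0, len(library), 4096):
                stop = min(start + 4096, len(library))
                chunk_counts = counts[start:stop, i]
                if chunk_counts.sum() == 0:
                    continue
                clean = [
                    template.build_read(barcode, library.dna[m])
                    for m in range(start, stop)
                    if counts[m, i] > 0
                ]
                reps = chunk_counts[chunk_counts > 0]
                block = (
                    np.frombuffer("".join(clean).encode(), dtype=np.uint8)
                    .reshape(len(clean), template.read_length)
                )
                block = np.repeat(block, reps, axis=0)
                block = _mutate_reads(block, config.substitution_error_rate, rng)
                for row in block:
                    fh.write(
                        f"@sim_{genotype}_{bin_id}_{serial}\n"
                        f"{row.tobytes().decode()}\n+\n{qual_line}\n"
                    )
                    serial += 1
    truth_path = outdir / f"{genotype}_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "fastq": fastq_paths,
        "truth": truth_path,
        "counts": counts_df,
        "library": library,
    }


# ---------------------------------------------------------------------------
# shipped effect-model presets


def single_effect_model(
    residue: str = "F",
    position: int = 1,
    effect: float = -1.0,
    baseline: float = 3.5,
    clps_dependent: bool = True,
) -> EffectModel:
    """An EffectModel with exactly one residue-position effect, optionally
    suppressed in the ClpS knockout.  The workhorse of parameter-recovery
    tests."""
    key = (residue, position)
    masks: dict[str, set] = {"CLPS_KO": {key}} if clps_dependent else {}
    return EffectModel(
        baseline=baseline, residue_effects={key: effect}, genotype_masks=masks
    )


def example_effect_model(include_pairs: bool = True) -> EffectModel:
    """A qualitative ground-truth preset for end-to-end demonstrations.

    Encodes, as injectable effects, the broad strokes of known N-degron
    behaviour: bulky/basic P1 residues destabilize through ClpS (directly or
    via LFTR-mediated Leu/Phe addition for Arg/Lys), P2 Pro and Gly stabilize,
    P2 Gln destabilizes, downstream bulky residues destabilize and acidic
    residues stabilize.  The magnitudes are plausible round numbers, not
    measured quantities.
    """
    clps = set()
    lftr = set()
    residue_effects: dict[EffectKey, float] = {}

    def add(residue: str, position: int, value: float, via: str | None) -> None:
        key = (residue, position)
        residue_effects[key] = value
        if via in ("clps", "both"):
            clps.add(key)
        if via in ("lftr", "both"):
            lftr.add(key)

    # P1: bulky residues bind ClpS directly; Arg/Lys require LFTR to create a
    # ClpS substrate, so both knockouts suppress them.
    add("F", 1, -1.3, "clps")
    add("R", 1, -1.3, "both")
    add("L", 1, -1.0, "clps")
    add("W", 1, -0.85, "clps")
    add("Y", 1, -0.85, "clps")
    add("K", 1, -0.85, "both")
    # P2 single-residue determinants.
    add("P", 2, 0.5, "clps")
    add("G", 2, 0.35, "clps")
    add("Q", 2, -0.5, "clps")
    # downstream bulky destabilization and acidic stabilization (P2-P5)
    for pos in (2, 3, 4, 5):
        for residue in "FLWY":
            if (residue, pos) not in residue_effects:
                add(residue, pos, -0.25, "clps")
        for residue in "DE":
            add(residue, pos, 0.2, "clps")
        for residue in "GS":
            if (residue, pos) not in residue_effects:
                add(residue, pos, 0.15, "clps")
    pair_effects: dict[PairKey, float] = {}
    if include_pairs:
        # clustered bulky P2/P3 destabilization beyond additivity for a
        # canonically stable P1 Cys, and a Cys1-Glu3 interaction.
        pair_effects[(("C", 1), ("E", 3))] = -0.4
        pair_effects[(("W", 2), ("W", 3))] = -0.3
        clps.update(pair_effects)
    return EffectModel(
        baseline=3.5,
        residue_effects=residue_effects,
        pair_effects=pair_effects,
        genotype_masks={"CLPS_KO": clps, "LFTR_KO": lftr},
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["template"] = dataclasses.asdict(config.template)
    return d
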