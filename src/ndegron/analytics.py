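"""Comparative stability analytics over motif-PSI databases.

Everything here is a pure function of one or two :class:`~ndegron.psi.MotifDatabase`
objects: residue-by-position mean-PSI matrices and their genotype differences,
subset contrasts with Mann-Whitney U tests and Cliff's delta effect sizes,
enrichment matrices and fold-enrichment logos, N-terminal net-charge and
residue-group analytics, a Met-aminopeptidase position-shift comparison, and a
bulky-by-acidic cross-tabulation.

Conventions
-----------
* Residue rows follow the canonical alphabet ``ACDEFGHIKLMNPQRSTVWY``;
  positions are P1..P5 with P1 the N-terminal residue.
* Empty cells (no contributing motifs) are NaN with n = 0, never zero-filled.
* Effect sizes are reported both signed (delta) and as magnitude (es), with
  the star annotation driven by the magnitude bands:
  ``*`` p < 0.05 & ES 0-0.25, ``**`` 0.25-0.50, ``***`` 0.50-0.75,
  ``****`` 0.75-1.0, and ``ns`` otherwise.
* No multiple-testing correction is applied: raw p-values are reported next
  to effect sizes, and conclusions should lean on the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genetics import AA_ALPHABET
from .psi import MotifDatabase

POSITIONS = (1, 2, 3, 4, 5)

#: Canonical residue-group presets used throughout the grouped analyses.
GROUPS: dict[str, frozenset] = {
    "Negative": frozenset("DE"),
    "Positive": frozenset("RK"),
    "Hydrophobic": frozenset("AVILMFWY"),
    "Polar": frozenset("RNDQEKHSTYC"),
    "Aromatic": frozenset("FWYH"),
    "Small": frozenset("GASC"),
    "Flexible": frozenset("GSDN"),
    "Bulky": frozenset("FLWY"),
    "CanonicalDestabilizing": frozenset("FLWYRK"),
}


# ---------------------------------------------------------------------------
# residue-by-position matrices


@dataclass
class ResiduePositionMatrix:
    """A 20 x k summary keyed by (residue, position).

    ``values`` and ``n`` are DataFrames indexed by residue (canonical order)
    with position columns (``P1``..); ``n`` counts contributing motifs.
    """

    values: pd.DataFrame
    n: pd.DataFrame
    statistic: str = "mean PSI"

    @property
    def positions(self) -> list[str]:
        return list(self.values.columns)

    def cell(self, residue: str, position: int) -> float:
        return float(self.values.loc[residue, f"P{position}"])

    def to_tsv(self, path, **provenance) -> None:
        with open(path, "w") as fh:
            items = "\t".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# statistic={self.statistic}" + ("\t" + items if items else "") + "\n")
            self.values.rename_axis("residue").to_csv(fh, sep="\t")


def _positional_frame(db: MotifDatabase, positions=POSITIONS) -> pd.DataFrame:
    """Long frame with one row per (motif, position): residue and psi."""
    frames = []
    motifs = db.records["motif"]
    for p in positions:
        frames.append(
            pd.DataFrame(
                {
                    "position": f"P{p}",
                    "residue": motifs.str[p - 1],
                    "psi": db.records["psi"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def mean_psi_matrix(
    db: MotifDatabase, positions=POSITIONS, statistic: str = "mean PSI"
) -> ResiduePositionMatrix:
    """Mean PSI over motifs carrying each residue at each position."""
    if len(db) == 0:
        raise ValueError("database is empty")
    long = _positional_frame(db, positions)
    grouped = long.groupby(["residue", "position"], sort=False)["psi"]
    mean = grouped.mean().unstack("position")
    count = grouped.size().unstack("position")
    cols = [f"P{p}" for p in positions]
    residues = list(AA_ALPHABET)
    values = mean.reindex(index=residues, columns=cols)
    n = count.reindex(index=residues, columns=cols).fillna(0).astype(int)
    return ResiduePositionMatrix(values=values, n=n, statistic=statistic)


def delta_matrix(a: ResiduePositionMatrix, b: ResiduePositionMatrix) -> ResiduePositionMatrix:
    """Cellwise ``a - b`` (e.g. WT minus knockout mean-PSI matrices).

    A cell empty in either operand is empty in the result; n is the cellwise
    minimum.  Antisymmetric: ``delta_matrix(a, b).values == -delta_matrix(b, a).values``.
    """
    if list(a.values.columns) != list(b.values.columns):
        raise ValueError("matrices must share the same position keying")
    values = a.values - b.values
    n = np.minimum(a.n, b.n)
    values = values.where(n > 0)
    return ResiduePositionMatrix(values=values, n=n, statistic="delta PSI")


def conditional_matrix(
    db: MotifDatabase, position: int, residue: str
) -> ResiduePositionMatrix:
    """Mean-PSI matrix over the four remaining positions, restricted to
    motifs with ``residue`` at ``position`` (e.g. the P2-P5 preferences of
    each P1 residue)."""
    mask = db.records["motif"].str[position - 1] == residue
    sub = MotifDatabase(
        genotype=db.genotype,
        records=db.records.loc[mask].reset_index(drop=True),
        normalization_mode=db.normalization_mode,
        min_reads_applied=db.min_reads_applied,
    )
    other = tuple(p for p in POSITIONS if p != position)
    if len(sub) == 0:
        cols = [f"P{p}" for p in other]
        empty = pd.DataFrame(np.nan, index=list(AA_ALPHABET), columns=cols)
        return ResiduePositionMatrix(
            values=empty, n=empty.fillna(0).astype(int), statistic="mean PSI"
        )
    return mean_psi_matrix(sub, positions=other)


# ---------------------------------------------------------------------------
# nonparametric contrasts


@dataclass
class StatResult:
    """Mann-Whitney U contrast between two PSI samples with Cliff's delta."""

    n1: int
    n2: int
    U: float
    p: float
    delta: float
    mean_diff: float
    annotation: str = ""
    es: float = field(init=False)

    def __post_init__(self) -> None:
        self.es = abs(self.delta)
        if not self.annotation:
            self.annotation = star_annotation(self.p, self.es)


def star_annotation(p: float, es: float) -> str:
    """Significance stars: gated on p < 0.05, tiered by effect-size
    magnitude (0-0.25 *, 0.25-0.50 **, 0.50-0.75 ***, 0.75-1.0 ****)."""
    if not (p < 0.05):
        return "ns"
    if es < 0.25:
        return "*"
    if es < 0.50:
        return "**"
    if es < 0.75:
        return "***"
    return "****"


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(X > Y) - P(X < Y) over all cross pairs, in [-1, 1].

    Computed from the midrank Mann-Whitney statistic, ``2 U / (n1 n2) - 1``,
    which equals the all-pairs definition with ties counted half each way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    return float(2.0 * u / (x.size * y.size) - 1.0)


def contrast(x, y) -> StatResult:
    """Two-sided Mann-Whitney U contrast of two PSI samples.

    Uses exact enumeration when ``min(n1, n2) <= 8`` and the pooled data is
    tie-free, otherwise the normal approximation with midranks and tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    delta = float(2.0 * res.statistic / (x.size * y.size) - 1.0)
    return StatResult(
        n1=int(x.size),
        n2=int(y.size),
        U=float(res.statistic),
        p=float(res.pvalue),
        delta=delta,
        mean_diff=float(x.mean() - y.mean()),
    )


def _resolve_mask(db: MotifDatabase, predicate) -> np.ndarray:
    if callable(predicate):
        return db.records["motif"].map(predicate).to_numpy(dtype=bool)
    return np.asarray(predicate, dtype=bool)


def subset_contrast(db: MotifDatabase, predicate_a, predicate_b) -> StatResult:
    """Contrast PSI between two motif subsets of one database.

    Predicates are callables over the motif string (or boolean masks).  Both
    subsets must be non-empty.
    """
    mask_a = _resolve_mask(db, predicate_a)
    mask_b = _resolve_mask(db, predicate_b)
    psi = db.records["psi"].to_numpy()
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both subsets must be non-empty")
    return contrast(psi[mask_a], psi[mask_b])


# ---------------------------------------------------------------------------
# sequence-property analytics

_CHARGE = {"R": 1, "K": 1, "D": -1, "E": -1}  # His deliberately uncharged


def net_charge(motif: str, positions=None) -> int:
    """Net side-chain charge: +1 per R/K, -1 per D/E, 0 otherwise (His
    counts 0; termini contribute nothing).  ``positions`` optionally
    restricts the sum (1-based, e.g. ``(2, 3, 4, 5)`` for P2-P5)."""
    if positions is None:
        positions = range(1, len(motif) + 1)
    return sum(_CHARGE.get(motif[p - 1], 0) for p in positions)


def group_count(motif: str, group, positions=None) -> int:
    """Count residues of ``group`` (a name from :data:`GROUPS` or an explicit
    residue set) at the stated 1-based positions of ``motif``."""
    members = GROUPS[group] if isinstance(group, str) else frozenset(group)
    if positions is None:
        positions = range(1, len(motif) + 1)
    return sum(1 for p in positions if motif[p - 1] in members)


# ---------------------------------------------------------------------------
# enrichment


def _position_frequencies(motifs: pd.Series) -> pd.DataFrame:
    """Residue frequency at each position; rows = residues, cols = P1..P5."""
    out = {}
    for p in POSITIONS:
        counts = motifs.str[p - 1].value_counts()
        out[f"P{p}"] = counts.reindex(list(AA_ALPHABET)).fillna(0) / len(motifs)
    return pd.DataFrame(out)


def enrichment_logo(
    subset_db: MotifDatabase, background_db: MotifDatabase
) -> ResiduePositionMatrix:
    """Fold enrichment of each residue at each position in ``subset_db``
    relative to ``background_db`` (a position-weight matrix suitable for logo
    rendering).  Cells with zero background frequency are NaN."""
    if len(subset_db) == 0 or len(background_db) == 0:
        raise ValueError("both databases must be non-empty")
    f_sub = _position_frequencies(subset_db.records["motif"])
    f_bg = _position_frequencies(background_db.records["motif"])
    fold = f_sub / f_bg.where(f_bg > 0)
    n = pd.DataFrame(
        np.minimum(
            (f_sub * len(subset_db)).to_numpy(),
            (f_bg * len(background_db)).to_numpy(),
        ).astype(int),
        index=f_sub.index,
        columns=f_sub.columns,
    )
    return ResiduePositionMatrix(values=fold, n=n, statistic="fold enrichment")


def p1p2_enrichment(
    db: MotifDatabase, stable_thr: float = 3.0, unstable_thr: float = 2.0
) -> pd.DataFrame:
    """Log2 stable/unstable enrichment for every ordered P1-P2 dipeptide.

    The stable stratum is PSI > ``stable_thr``, the unstable stratum
    PSI < ``unstable_thr``.  Each pair's count is normalised by its stratum
    size (frequency normalisation, deterministic) before taking the log2
    ratio.  Returns a 20 x 20 DataFrame (rows = P1, cols = P2); pairs absent
    from either stratum are NaN.
    """
    psi = db.records["psi"]
    stable = db.records.loc[psi > stable_thr, "motif"]
    unstable = db.records.loc[psi < unstable_thr, "motif"]
    if len(stable) == 0 or len(unstable) == 0:
        raise ValueError("both PSI strata must be non-empty")

    def pair_freq(motifs: pd.Series) -> pd.DataFrame:
        pairs = motifs.str[:2].value_counts()
        mat = pd.DataFrame(
            0.0, index=list(AA_ALPHABET), columns=list(AA_ALPHABET)
        )
        for pair, count in pairs.items():
            mat.loc[pair[0], pair[1]] = count
        return mat / len(motifs)

    f_stable = pair_freq(stable)
    f_unstable = pair_freq(unstable)
    ratio = f_stable.where(f_stable > 0) / f_unstable.where(f_unstable > 0)
    out = np.log2(ratio)
    out.index.name = "P1"
    out.columns.name = "P2"
    return out


def rank_low_psi_pairs(db: MotifDatabase, k: int = 100, by: str = "mean_psi") -> pd.DataFrame:
    """The ``k`` lowest-stability P1/P2 dipeptides, ranked by mean PSI per
    pair (default) or, with ``by='enrichment'``, by the log2 stable/unstable
    enrichment of :func:`p1p2_enrichment`."""
    if by == "mean_psi":
        pairs = db.records["motif"].str[:2]
        stat = db.records.groupby(pairs)["psi"].mean().rename("mean_psi")
        out = stat.sort_values().head(k).reset_index().rename(columns={"motif": "pair"})
    elif by == "enrichment":
        mat = p1p2_enrichment(db)
        long = mat.stack().rename("log2_enrichment").reset_index()
        long["pair"] = long["P1"] + long["P2"]
        out = long.sort_values("log2_enrichment").head(k)[["pair", "log2_enrichment"]]
        out = out.reset_index(drop=True)
    else:
        raise ValueError("by must be 'mean_psi' or 'enrichment'")
    return out


# ---------------------------------------------------------------------------
# Met-aminopeptidase comparison


def metap_comparison(db: MotifDatabase) -> pd.DataFrame:
    """Compare mean PSI of Met-initiated motifs (M-X-Y-Y-Y) against the same
    four-residue windows shifted to the N-terminus (X-Y-Y-Y-Z), per residue X.

    For each 4-mer ``w`` following an N-terminal Met, the shifted comparison
    set is every motif whose first four residues equal ``w`` (any fifth
    residue).  Windows present on only one side are dropped, then means are
    aggregated per X = w[0].  A positive ``diff`` means the Met-extended form
    is the stabler one, i.e. Met excision would expose a more degradable
    N-terminus.
    """
    records = db.records
    motifs = records["motif"]
    met = records.loc[motifs.str[0] == "M"].copy()
    if len(met) == 0:
        raise ValueError("database contains no P1-Met motifs")
    met["window"] = met["motif"].str[1:5]
    shifted = records.copy()
    shifted["window"] = shifted["motif"].str[0:4]
    met_means = met.groupby("window")["psi"].agg(["mean", "size"])
    shifted_means = shifted.groupby("window")["psi"].agg(["mean", "size"])
    joined = met_means.join(
        shifted_means, how="inner", lsuffix="_met", rsuffix="_shifted"
    ).reset_index()
    joined["X"] = joined["window"].str[0]
    per_x = joined.groupby("X").agg(
        mean_psi_met=("mean_met", "mean"),
        mean_psi_shifted=("mean_shifted", "mean"),
        n_windows=("window", "size"),
    )
    per_x["diff"] = per_x["mean_psi_met"] - per_x["mean_psi_shifted"]
    return per_x.reset_index()


# ---------------------------------------------------------------------------
# bulky x negative cross-tabulation


def crosstab_bulky_negative(
    db: MotifDatabase, p1_filter=None
) -> tuple[pd.DataFrame, dict[tuple[int, int], StatResult]]:
    """Mean PSI change by (count of P2-P5 bulky FLWY, count of P2-P5 acidic
    DE), relative to the (0, 0) cell.

    ``p1_filter`` optionally restricts the motifs (callable over the motif
    string), e.g. to canonically stable P1 residues.  Returns the delta-PSI
    matrix (NaN for empty cells) and a per-cell :class:`StatResult` against
    the reference cell.
    """
    records = db.records
    if p1_filter is not None:
        records = records.loc[records["motif"].map(p1_filter)]
    if len(records) == 0:
        raise ValueError("no motifs pass the P1 filter")
    tail = (2, 3, 4, 5)
    bulky = records["motif"].map(lambda m: group_count(m, "Bulky", tail))
    acidic = records["motif"].map(lambda m: group_count(m, "Negative", tail))
    psi = records["psi"]
    ref = psi[(bulky == 0) & (acidic == 0)]
    if len(ref) == 0:
        raise ValueError("reference cell (0 bulky, 0 acidic) is empty")
    ref_mean = ref.mean()
    table = pd.DataFrame(np.nan, index=range(5), columns=range(5))
    table.index.name = "n_bulky_p2p5"
    table.columns.name = "n_negative_p2p5"
    stats: dict[tuple[int, int], StatResult] = {}
    for (nb, na), cell_psi in psi.groupby([bulky, acidic]):
        table.loc[nb, na] = cell_psi.mean() - ref_mean
        if (nb, na) != (0, 0):
            stats[(nb, na)] = contrast(cell_psi.to_numpy(), ref.to_numpy())
    return table, stats


# ---------------------------------------------------------------------------
# grouped-property enrichment


def group_enrichment(
    subset_db: MotifDatabase,
    background_db: MotifDatabase,
    groups: dict[str, frozenset] | None = None,
) -> pd.DataFrame:
    """Per-position difference in mean group occurrence between a subset
    (e.g. low-PSI motifs) and the background: positive values mean the group
    is over-represented at that position in the subset."""
    groups = GROUPS if groups is None else groups
    f_sub = _position_frequencies(subset_db.records["motif"])
    f_bg = _position_frequencies(background_db.records["motif"])
    rows = {}
    for name, members in groups.items():
        idx = [aa for aa in AA_ALPHABET if aa in members]
        rows[name] = f_sub.loc[idx].sum() - f_bg.loc[idx].sum()
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out
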