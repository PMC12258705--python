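#!/usr/bin/env python
"""Comparative stability analytics on the simulated genotype panel.

Recomputes, at desk scale, the analytic battery the PSI databases feed:
residue-by-position mean-PSI matrices and their WT-minus-knockout
differences, P2 Pro/Gln subset contrasts with Mann-Whitney U and Cliff's
delta, net-charge and Gly/Ser-count trends, P1/P2 dipeptide enrichment, the
bulky-by-acidic cross-tabulation, and the Met-aminopeptidase position-shift
comparison.  Tables land under results/analysis/.
"""

from pathlib import Path

import numpy as np

from ndegron.analytics import (
    GROUPS,
    crosstab_bulky_negative,
    delta_matrix,
    enrichment_logo,
    group_count,
    mean_psi_matrix,
    metap_comparison,
    net_charge,
    p1p2_enrichment,
    subset_contrast,
)
from ndegron.psi import MotifDatabase

ROOT = Path(__file__).resolve().parents[1]
PSI = ROOT / "results" / "psi"
OUTDIR = ROOT / "results" / "analysis"

DESTAB = GROUPS["CanonicalDestabilizing"]


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    dbs = {
        g: MotifDatabase.from_tsv(PSI / f"{g}_psi.tsv")
        for g in ("WT", "CLPS_KO", "LFTR_KO")
    }
    matrices = {g: mean_psi_matrix(db) for g, db in dbs.items()}
    for g, matrix in matrices.items():
        matrix.to_tsv(OUTDIR / f"{g}_mean_psi_matrix.tsv", genotype=g)

    # genotype differences: ClpS dependence dominates P1
    for ko in ("CLPS_KO", "LFTR_KO"):
        delta = delta_matrix(matrices["WT"], matrices[ko])
        delta.to_tsv(OUTDIR / f"WT_minus_{ko}_delta_psi.tsv")
        p1 = delta.values["P1"]
        print(f"WT - {ko}: strongest P1 shifts "
              f"{p1.sort_values().head(3).round(2).to_dict()}")

    wt = dbs["WT"]

    # P2 subset contrasts against all other P2 residues, destabilizing P1 only
    for residue in ("P", "G", "Q", "A"):
        res = subset_contrast(
            wt,
            lambda m, r=residue: m[0] in DESTAB and m[1] == r,
            lambda m, r=residue: m[0] in DESTAB and m[1] != r,
        )
        print(f"P2 {residue} vs other P2 (P1 FLWYRK): mean diff "
              f"{res.mean_diff:+.2f} PSI, ES {res.es:.2f}, p {res.p:.2e} "
              f"{res.annotation}")

    # net-charge trend
    charge = wt.records["motif"].map(net_charge)
    trend = wt.records.groupby(charge)["psi"].agg(["mean", "size"])
    trend.rename_axis("net_charge").to_csv(OUTDIR / "WT_psi_by_net_charge.tsv", sep="\t")
    print("mean PSI by net charge:",
          {int(k): round(v, 2) for k, v in trend["mean"].items()})

    # Gly/Ser count downstream of a destabilizing P1
    sub = wt.records[wt.records["motif"].str[0].isin(list(DESTAB))]
    gs = sub["motif"].map(lambda m: group_count(m, frozenset("GS"), (2, 3, 4, 5)))
    gs_trend = sub.groupby(gs)["psi"].mean()
    base = gs_trend.get(0, np.nan)
    print("PSI increase vs 0 Gly/Ser (P1 FLWYRK):",
          {int(k): round(float(v - base), 2) for k, v in gs_trend.items() if k > 0})

    # P1/P2 dipeptide enrichment and low-PSI logo
    enrichment = p1p2_enrichment(wt, stable_thr=3.0, unstable_thr=2.0)
    enrichment.to_csv(OUTDIR / "WT_p1p2_log2_enrichment.tsv", sep="\t")
    low = wt.records["psi"] < 3.0
    low_db = MotifDatabase("WT", wt.records[low].reset_index(drop=True))
    logo = enrichment_logo(low_db, wt)
    logo.to_tsv(OUTDIR / "WT_lowpsi_fold_enrichment_logo.tsv", threshold="psi<3")

    # bulky x acidic cross-tabulation for canonically stable P1
    crosstab, _ = crosstab_bulky_negative(wt, p1_filter=lambda m: m[0] not in DESTAB)
    crosstab.to_csv(OUTDIR / "WT_bulky_x_negative_delta_psi.tsv", sep="\t")

    # Met-aminopeptidase comparison
    metap = metap_comparison(wt)
    metap.to_csv(OUTDIR / "WT_metap_comparison.tsv", sep="\t", index=False)
    indexed = metap.set_index("X")
    present = [r for r in DESTAB if r in indexed.index]
    print("MXYYY minus XYYYZ mean-PSI difference for destabilizing X "
          "(n matched windows):",
          {r: (round(float(indexed.loc[r, 'diff']), 2),
               int(indexed.loc[r, 'n_windows'])) for r in present})
    print(f"wrote analytic tables to {OUTDIR}")


if __name__ == "__main__":
    main()
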