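#!/usr/bin/env python
"""Random-effects meta-analysis of EP-mortality odds ratios.

Pools (1) the published stage-adjusted 12-month ORs of the 12 fully
staged jurisdictions, with the broad/narrow definition type as a
moderator — the central replication target — and (2) the synthetic
per-jurisdiction estimates produced by 04_association_models.py, where
the generating conditional OR is 3.0.  Writes MetaResult JSONs and a
forest plot (scratch/, since figures are not text artefacts).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import ep_routes as ep
from ep_routes.published import stage_adjusted_study_estimates

ROOT = Path(__file__).resolve().parents[1]


def forest_plot(estimates, result, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(7, 0.45 * len(estimates) + 2))
    ys = np.arange(len(estimates))[::-1]
    for y, e in zip(ys, estimates):
        lo, hi = ep.EffectEstimate("x", e.log_or, e.se).ci_low, ep.EffectEstimate("x", e.log_or, e.se).ci_high
        ax.plot([lo, hi], [y, y], "k-")
        ax.plot(np.exp(e.log_or), y, "ks", ms=5)
        ax.text(0.02, y, f"{e.jurisdiction} ({e.definition_type})",
                transform=ax.get_yaxis_transform(), va="center", fontsize=8)
    for i, (level, pooled) in enumerate(result.pooled.items()):
        lo, hi = pooled.ci
        ax.errorbar(pooled.or_, -1.2 - i, xerr=[[pooled.or_ - lo], [hi - pooled.or_]],
                    fmt="D", color="tab:blue")
        ax.text(0.02, -1.2 - i, f"pooled ({level})",
                transform=ax.get_yaxis_transform(), va="center", fontsize=8,
                color="tab:blue")
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("12-month mortality OR (EP vs non-EP), log scale")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def main():
    argparse.ArgumentParser().parse_args()
    outdir = ROOT / "results"
    figdir = ROOT / "scratch" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    published = stage_adjusted_study_estimates()
    res = ep.pool_random_effects(published, moderator=True)
    res_unmod = ep.pool_random_effects(published)
    payload = {"moderated": res.to_dict(), "unmoderated": res_unmod.to_dict()}
    with open(outdir / "meta_published.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    b, n = res.pooled["broad"], res.pooled["narrow"]
    print(f"published pooled OR, broad  {b.or_:.2f} ({b.ci[0]:.2f}-{b.ci[1]:.2f})")
    print(f"published pooled OR, narrow {n.or_:.2f} ({n.ci[0]:.2f}-{n.ci[1]:.2f})")
    print(f"residual heterogeneity I2 = {res.i2_tau2:.0f}% (tau2 {res.tau2:.4f})")
    forest_plot(published, res, figdir / "forest_published.png")

    est = pd.read_csv(ROOT / "results" / "synthetic_ep_estimates.csv")
    rows = est[
        (est["model"] == "mortality_adj_stage")
        & (est["horizon"] == "12m")
        & (est["term"] == "ep_status=True")
    ]
    # definition type of each synthetic jurisdiction travels in the
    # estimates via the labelling definition used per jurisdiction
    cfg = ep.SimulationConfig.from_json(ROOT / "scratch" / "synthetic" / "config.json")
    deftypes = {j.name: j.definition_type for j in cfg.jurisdictions}
    synth = [
        ep.StudyEstimate(r.jurisdiction, r.log_or, r.se, deftypes[r.jurisdiction])
        for r in rows.itertuples()
    ]
    res_s = ep.pool_random_effects(synth, moderator=True)
    with open(outdir / "meta_synthetic.json", "w") as fh:
        json.dump(res_s.to_dict(), fh, indent=2)
    bs, ns = res_s.pooled["broad"], res_s.pooled["narrow"]
    print(f"\nsynthetic pooled OR (generating 3.0): broad {bs.or_:.2f} "
          f"({bs.ci[0]:.2f}-{bs.ci[1]:.2f}), narrow {ns.or_:.2f} "
          f"({ns.ci[0]:.2f}-{ns.ci[1]:.2f})")


if __name__ == "__main__":
    main()
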