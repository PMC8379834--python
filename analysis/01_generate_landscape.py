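"""Generate the synthetic study landscape and write it to disk.

Produces the household census (two strata: a dense urban core and a
sparse rural remainder), the provider census with readiness checklists,
the road network, and the admin polygon. Prints the headline composition
so the landscape can be eyeballed against the intended study structure
(335 rural / 469 urban households, ~7 provider categories dominated by
government health centers).
"""

import argparse
from collections import Counter
from pathlib import Path

from geolink_coverage.config import LandscapeConfig, save_config
from geolink_coverage.io import write_landscape
from geolink_coverage.landscape import generate_landscape


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/landscape"))
    args = ap.parse_args()

    config = LandscapeConfig()
    land = generate_landscape(config, args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    write_landscape(land, args.out)
    save_config(config, args.out / "landscape_config.yaml")

    strata = Counter(h.stratum for h in land.households)
    children = sum(h.n_children_u5 for h in land.households)
    print(f"households: {dict(strata)} (total {len(land.households)}), "
          f"{children} children under 5")
    cats = Counter(p.category for p in land.providers)
    for cat, n in sorted(cats.items()):
        print(f"  providers/{cat}: {n}")
    print(f"roads: {len(land.roads.nodes)} nodes, {len(land.roads.edges)} edges")
    print(f"written to {args.out}/")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 6))
        for a, b, _, cls_ in land.roads.edges:
            xs, ys = zip(land.roads.nodes[a], land.roads.nodes[b])
            ax.plot(xs, ys, color={"paved": "k", "graded": "gray", "footpath": "0.85"}[cls_],
                    lw={"paved": 2, "graded": 1.2, "footpath": 0.5}[cls_], zorder=1)
        for stratum, color in (("rural", "tab:green"), ("urban", "tab:orange")):
            pts = [(h.x, h.y) for h in land.households if h.stratum == stratum]
            ax.scatter(*zip(*pts), s=4, color=color, label=f"{stratum} household", zorder=2)
        ax.scatter([p.x for p in land.providers], [p.y for p in land.providers],
                   s=30, marker="^", color="tab:red", label="provider", zorder=3)
        ax.legend(loc="upper right", fontsize=8)
        ax.set_aspect("equal")
        fig.savefig(args.out / "landscape_qc.png", dpi=120, bbox_inches="tight")
        print(f"QC map: {args.out}/landscape_qc.png")
    except ImportError:
        print("matplotlib not available; skipping QC map")


if __name__ == "__main__":
    main()
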