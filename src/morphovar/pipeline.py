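"""End-to-end analysis pipeline.

``run_full_analysis`` sequences the whole study on one coefficient table:
the three ordinations with their variance shares and group-mean
configurations, the pairwise Protest matrix (optionally against an
external configuration such as a PCoA of a genetic distance matrix), the
Pmax report for well-sampled groups with pairwise comparisons, the
homogenized-variance simulation study, and a JSON run manifest that
suffices to re-run the analysis identically.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import GroupedDataset, read_fc_table
from .ordination import bgpca, cva, pca, pcoa, read_distance_matrix
from .pmax import WELL_SAMPLED_N, bootstrap_pmax, compare_pmax
from .protest import protest
from .simulation import simulation_study
from ._warnings import SmallSampleWarning

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of a full run; defaults follow the study design
    (4 retained axes, 100 bootstrap replicates, 999 permutations and
    simulation replicates, group size >= 30 for Pmax)."""

    input_table: str
    output_dir: str
    n_axes: int = 4
    n_boot: int = 100
    n_perm: int = 999
    n_sim: int = 999
    seed: int = 0
    pmax_min_n: int = WELL_SAMPLED_N
    distance_matrix: str | None = None
    simulation_groups: list[str] | None = None
    merge_map: dict[str, str] | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_axes < 2:
            raise ValueError("need at least 2 axes")
        for name in ("n_boot", "n_perm", "n_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _write_ordination(result, outdir: Path, n_axes: int) -> None:
    prefix = outdir / result.method.lower()
    result.summary().to_csv(f"{prefix}_eigen.tsv", sep="\t", index=False)
    cfg = result.configuration(n_axes)
    pd.DataFrame(
        cfg.coords, index=cfg.labels, columns=[f"axis{i+1}" for i in range(cfg.k)]
    ).to_csv(f"{prefix}_group_means.tsv", sep="\t")
    if result.loadings is not None:
        pd.DataFrame(
            result.loadings, columns=[f"axis{i+1}" for i in range(result.loadings.shape[1])]
        ).to_csv(f"{prefix}_loadings.tsv", sep="\t", index=False)


def run_full_analysis(config: AnalysisConfig, data: GroupedDataset | None = None) -> dict:
    """Run the complete study; returns a summary dict (also written as
    ``manifest.json``).  Any stage failure aborts with the stage name and
    leaves a ``FAILED`` marker next to the partial outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read-input"
    summary: dict = {
        "package_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
    }
    try:
        if data is None:
            data = read_fc_table(config.input_table)
        if config.merge_map:
            data = data.merge_groups(config.merge_map)
        log.info("loaded %d specimens in %d groups", data.n_specimens, data.n_groups)

        stage = "ordination"
        results = {
            "PCA": pca(data, config.n_axes),
            "bgPCA": bgpca(data, config.n_axes),
            "CVA": cva(data, config.n_axes),
        }
        for res in results.values():
            _write_ordination(res, outdir, config.n_axes)
        summary["percent_variance"] = {
            m: [round(float(x), 4) for x in r.percent_variance[: config.n_axes]]
            for m, r in results.items()
        }

        stage = "protest"
        configs = {m: r.configuration(config.n_axes) for m, r in results.items()}
        if config.distance_matrix:
            dist = read_distance_matrix(config.distance_matrix)
            configs["PCoA"] = pcoa(dist, config.n_axes).configuration(config.n_axes)
        rows = []
        for a, b in itertools.combinations(configs, 2):
            res = protest(configs[a], configs[b], config.n_perm, seed=config.seed)
            rows.append({"x": a, "y": b, "d": res.d, "r": res.r, "p": res.p_value})
        protest_table = pd.DataFrame(rows)
        protest_table.to_csv(outdir / "protest.tsv", sep="\t", index=False)
        summary["protest"] = rows

        stage = "pmax"
        well_sampled = [
            g for g, n in data.group_sizes().items() if n >= config.pmax_min_n
        ]
        estimates = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallSampleWarning)
            for g in well_sampled:
                estimates[g] = bootstrap_pmax(
                    data.group_values(g), config.n_boot, seed=config.seed, group_id=g
                )
        pd.DataFrame(
            {
                "group": list(estimates),
                "n": [e.n_specimens for e in estimates.values()],
                "percent_lambda1": [e.percent_first_eigenvalue for e in estimates.values()],
                "r95": [e.r95 for e in estimates.values()],
            }
        ).to_csv(outdir / "pmax_groups.tsv", sep="\t", index=False)
        comp_rows = []
        for a, b in itertools.combinations(estimates, 2):
            c = compare_pmax(estimates[a], estimates[b])
            comp_rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "r_between": c.r_between,
                    "threshold": c.threshold,
                    "distinguishable": c.distinguishable,
                }
            )
        pd.DataFrame(comp_rows).to_csv(outdir / "pmax_comparisons.tsv", sep="\t", index=False)
        summary["pmax"] = {
            "groups": {g: {"r95": e.r95, "percent_lambda1": e.percent_first_eigenvalue}
                       for g, e in estimates.items()},
            "comparisons": comp_rows,
        }

        stage = "simulation"
        sim = simulation_study(
            data,
            n_sim=config.n_sim,
            n_axes=config.n_axes,
            seed=config.seed,
            groups=config.simulation_groups,
        )
        sim_rows = []
        for (a, b), out in sim.pairs.items():
            sim_rows.append(
                {
                    "x": a,
                    "y": b,
                    "observed_d": out.observed_d,
                    "observed_quantile": out.observed_quantile,
                    "null_mean_d": float(out.simulated_d.mean()),
                    "null_q975": float(np.quantile(out.simulated_d, 0.975)),
                }
            )
            np.savetxt(
                outdir / f"simulated_d_{a}_{b}.txt", out.simulated_d, fmt="%.10g"
            )
        pd.DataFrame(sim_rows).to_csv(outdir / "simulation.tsv", sep="\t", index=False)
        summary["simulation"] = sim_rows

        if config.make_plots:
            stage = "plots"
            from . import plots

            for m, r in results.items():
                plots.plot_configuration(r, path=outdir / f"{m.lower()}_config.png")
            plots.plot_simulation(sim, path=outdir / "simulation_hist.png")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
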