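"""The two in-silico odor experiments and the lateral-weight sweep.

* ``run_experiment1`` — 6 odors x 6 concentrations: simulate the 36
  exposures, read out MC and ET mean-rate matrices, and score identity
  coding (Fisher discriminant ratio of the population-mean rate against
  odor labels) and concentration coding (per-odor Pearson correlation
  against the concentration factors) for the MC output, the ET output and
  the raw input currents, plus mean-centred PCA of all three.
* ``run_morphing`` — the 21-step binary C->E mixture series together with
  the 36 stimuli of the first experiment (57 exposures); hierarchical
  bisecting-k-means dendrograms of inputs, MC output and ET output, and
  the MC PCA trajectory of the morph series.
* ``sa_weight_sweep`` — the two objectives as a function of the
  inter-glomerular short-axon weight, multi-seed, as a tidy table.

The identity objective is computed on the mean firing rate over glomeruli
(a scalar per exposure); the concentration objective pools (glomerulus,
concentration) pairs per odor. See docs/methods.md for why these
scalarizations are the calibrated reading of the two objectives.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from .network import (Network, NetworkConfig, build_glomerular_layer,
                      rates_from_counts, run_stimulus_batch)
from .stimuli import (OdorPanel, StimulusSet, build_experiment1,
                      build_morph_series, generate_odor_panel)

__all__ = [
    "ExperimentResult",
    "population_metrics",
    "run_experiment1",
    "run_morphing",
    "sa_weight_sweep",
    "sweep_summary",
]

DEFAULT_SEED = 1
DEFAULT_SWEEP_GRID = tuple(range(0, 31))


def population_metrics(X: np.ndarray, odors, concentrations,
                       with_pca: bool = True) -> dict:
    """Identity and concentration scores of one (stimuli x glomeruli) matrix.

    FDR is the trace-ratio discriminant of the mean-over-glomeruli scalar
    with odor identity as the class label; PCC is the per-odor pooled
    correlation against concentration (mean +/- sd across odors).
    """
    odors = np.asarray(odors)
    out: dict = {}
    try:
        out["fdr"] = mx.fisher_discriminant_ratio(X.mean(axis=1), odors)
    except (ValueError, mx.DegenerateDataError):
        out["fdr"] = float("nan")
    try:
        cc = mx.concentration_correlation(X, odors, concentrations)
        out["pcc_mean"], out["pcc_sd"] = cc.mean, cc.sd
        out["pcc_excluded"] = list(cc.excluded)
    except (ValueError, mx.DegenerateDataError):
        out["pcc_mean"] = out["pcc_sd"] = float("nan")
        out["pcc_excluded"] = []
    if with_pca and np.ptp(X) > 0:
        scores, evr = mx.pca_scores(X)
        out["pca_scores"] = scores
        out["pca_evr"] = evr
    return out


@dataclass
class ExperimentResult:
    """Everything one experiment produced, re-runnable from its snapshot."""

    name: str
    config: NetworkConfig
    seed: int
    stimuli: StimulusSet
    mc_rates: np.ndarray
    et_rates: np.ndarray
    metrics: dict
    dendrograms: dict = field(default_factory=dict)

    def stimulus_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stimulus_id": np.arange(len(self.stimuli)),
            "odor": self.stimuli.odors,
            "concentration": self.stimuli.concentrations,
        })

    def rates_frame(self, population: str) -> pd.DataFrame:
        X = {"MC": self.mc_rates, "ET": self.et_rates}[population]
        df = self.stimulus_frame()
        for g in range(X.shape[1]):
            df[f"rate_{g}"] = X[:, g]
        return df

    def save(self, out_dir) -> None:
        """Persist rate matrices, metrics and a run manifest as text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pop in ("MC", "ET"):
            self.rates_frame(pop).to_csv(out / f"{self.name}_{pop}_rates.tsv",
                                         sep="\t", index=False)
        self.stimuli.to_text(out / f"{self.name}_stimuli.tsv")
        summary = {
            pop: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                  for k, v in m.items() if k != "pca_scores"}
            for pop, m in self.metrics.items()
        }
        (out / f"{self.name}_metrics.json").write_text(
            json.dumps(summary, indent=2))
        for key, dendro in self.dendrograms.items():
            (out / f"{self.name}_{key}.nwk").write_text(dendro.to_newick() + "\n")
        manifest = {
            "experiment": self.name,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "versions": _versions(),
        }
        (out / f"{self.name}_manifest.json").write_text(
            json.dumps(manifest, indent=2))


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__
    return {"glomnet": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "pandas": pd.__version__}


def _simulate_rates(net: Network, stim_set: StimulusSet):
    counts = run_stimulus_batch(net, stim_set.R)
    dur = net.config.duration
    return (rates_from_counts(counts, net, "MC", dur),
            rates_from_counts(counts, net, "ET", dur))


def run_experiment1(config: NetworkConfig | None = None,
                    seed: int = DEFAULT_SEED,
                    panel: OdorPanel | None = None) -> ExperimentResult:
    """The 6-odors x 6-concentrations identity/concentration experiment."""
    config = config or NetworkConfig()
    if panel is None:
        panel = generate_odor_panel(6, config.n_glomeruli, seed=seed)
    stim = build_experiment1(panel)
    net = build_glomerular_layer(config)
    mc, et = _simulate_rates(net, stim)
    odors, conc = stim.odors, stim.concentrations
    metrics = {
        "MC": population_metrics(mc, odors, conc),
        "ET": population_metrics(et, odors, conc),
        "input": population_metrics(stim.R, odors, conc),
    }
    return ExperimentResult("exp1", config, seed, stim, mc, et, metrics)


def _morph_label(s) -> str:
    if s.odor == "mix":
        return f"mix_{s.concentration:.2f}"
    return f"{s.odor}_{s.concentration:g}"


def run_morphing(config: NetworkConfig | None = None,
                 seed: int = DEFAULT_SEED,
                 panel: OdorPanel | None = None) -> ExperimentResult:
    """The odor-morphing experiment: 21 C->E mixtures plus the 36 stimuli.

    Produces dendrograms of the input patterns and of the MC and ET rate
    matrices over all 57 exposures, and the MC PCA scores with the morph
    trajectory.
    """
    config = config or NetworkConfig()
    if panel is None:
        panel = generate_odor_panel(6, config.n_glomeruli, seed=seed)
    morph = build_morph_series(panel)
    exp1 = build_experiment1(panel)
    stim = StimulusSet(list(morph) + list(exp1))
    net = build_glomerular_layer(config)
    mc, et = _simulate_rates(net, stim)
    labels = [_morph_label(s) for s in stim]
    dendrograms = {
        "input_dendrogram": mx.hierarchical_kmeans(stim.R, labels, seed=seed),
        "MC_dendrogram": mx.hierarchical_kmeans(mc, labels, seed=seed),
        "ET_dendrogram": mx.hierarchical_kmeans(et, labels, seed=seed),
    }
    mc_scores, mc_evr = mx.pca_scores(mc)
    metrics = {
        "MC": {"pca_scores": mc_scores, "pca_evr": mc_evr,
               "morph_index": list(range(len(morph)))},
        "ET": {}, "input": {},
    }
    return ExperimentResult("morph", config, seed, stim, mc, et, metrics,
                            dendrograms)


def sa_weight_sweep(config: NetworkConfig | None = None,
                    weights=DEFAULT_SWEEP_GRID,
                    seeds=tuple(range(1, 11))) -> pd.DataFrame:
    """Objectives versus the short-axon lateral weight, multi-seed.

    Returns a tidy table with one row per (weight, seed): FDR and
    concentration PCC of the MC output, the ET output and the raw input,
    plus the ET PC1 explained-variance fraction and total MC spike count.
    Panels differ per seed; all seeds share each weight's network. The
    per-seed stimulus batches are stacked and simulated together (exposures
    are independent, so batching is exact).
    """
    config = config or NetworkConfig()
    weights = list(weights)
    seeds = list(seeds)
    if not weights:
        raise ValueError("weight grid must be non-empty")
    panels = [generate_odor_panel(6, config.n_glomeruli, seed=s) for s in seeds]
    stim_sets = [build_experiment1(p) for p in panels]
    R_all = np.vstack([st.R for st in stim_sets])
    n_per = len(stim_sets[0])
    rows = []
    for w in weights:
        cfg = dataclasses.replace(config, sa_weight=float(w))
        net = build_glomerular_layer(cfg)
        counts = run_stimulus_batch(net, R_all)
        for i, (seed, st) in enumerate(zip(seeds, stim_sets)):
            blk = counts[i * n_per:(i + 1) * n_per]
            mc = rates_from_counts(blk, net, "MC", cfg.duration)
            et = rates_from_counts(blk, net, "ET", cfg.duration)
            odors, conc = st.odors, st.concentrations
            row = {"sa_weight": float(w), "seed": seed,
                   "mc_spikes": int(blk[:, net.population_index("MC")].sum())}
            for name, X in (("mc", mc), ("et", et), ("input", st.R)):
                m = population_metrics(X, odors, conc, with_pca=False)
                row[f"{name}_fdr"] = m["fdr"]
                row[f"{name}_pcc"] = m["pcc_mean"]
            if np.ptp(et) > 0:
                _, evr = mx.pca_scores(et)
                row["et_pc1_evr"] = float(evr[0])
            else:
                row["et_pc1_evr"] = float("nan")
            if np.ptp(st.R) > 0:
                _, evr_in = mx.pca_scores(st.R)
                row["input_pc1_evr"] = float(evr_in[0])
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_summary(table: pd.DataFrame) -> dict:
    """Seed-averaged sweep curves and the location of the MC-FDR maximum."""
    mean = table.groupby("sa_weight").mean(numeric_only=True)
    argmax = float(mean["mc_fdr"].idxmax())
    at = mean.loc[argmax]
    return {
        "argmax_sa_weight": argmax,
        "mc_fdr_at_argmax": float(at["mc_fdr"]),
        "et_fdr_at_argmax": float(at["et_fdr"]),
        "input_fdr": float(mean["input_fdr"].mean()),
        "mc_pcc_at_argmax": float(at["mc_pcc"]),
        "et_pcc_at_argmax": float(at["et_pcc"]),
        "input_pcc": float(mean["input_pcc"].mean()),
        "et_pc1_evr_at_argmax": float(at["et_pc1_evr"]),
        "input_pc1_evr": float(mean["input_pc1_evr"].mean()),
        "curves": mean,
    }
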