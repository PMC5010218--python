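"""End-to-end orchestration of the decay-curve workflow and the simulations.

These functions glue the modules together in the fixed order
QC -> imputation -> pruning -> standardization -> clustering split ->
(rebalancing) -> swap series -> per-pair model fit/predict -> LOESS curve +
linear approximation.  Every random operation receives an explicit seed
derived from the run seed, and all seeds are written to the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decay as decay_mod
from .breeding_sim import (
    assign_trait,
    cross_population_experiment,
    phenotype as sim_phenotype,
    run_selection_program,
    uniform_map,
)
from .decay import DecayPoint, fit_decay_curve, fit_linear, plot_decay, points_to_csv
from .exceptions import GpdecayError, UndefinedCorrelationError
from .fst import fst_beta_binomial
from .genotype_io import (
    GenotypeMatrix,
    Phenotype,
    StandardizedMatrix,
    apply_qc,
    impute_missing,
    match_phenotype,
    prune_correlated,
    read_genotypes,
    read_phenotypes,
    standardize,
)
from .prediction import fit_elastic_net, holdout_cv, predict_phenotypes, predictive_correlation
from .subsetting import SubsetPair, generate_swap_series, rebalance, split_minimally_related

log = logging.getLogger("gpdecay")


def preprocess(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_max: float = 0.20,
    r_max: float = 0.95,
    k_neighbours: int = 10,
    seed: int = 0,
) -> GenotypeMatrix:
    """Fixed-order quality control: MAF/missingness filter, kNN imputation,
    LD pruning."""
    g = apply_qc(g, maf_min=maf_min, missing_max=missing_max)
    g = impute_missing(g, k_neighbours=k_neighbours, seed=seed)
    g = prune_correlated(g, r_max=r_max)
    return g


def decay_points_from_series(
    x: StandardizedMatrix,
    y: Phenotype,
    series,
    seed: int = 0,
    **fit_kwargs,
) -> list:
    """Fit a prediction model per subsample pair and collect
    (m, F_ST, rho_D(m)) decay points."""
    points = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(series.pairs)) % (2**31 - 1)
    for k, (pair, fst_val) in enumerate(zip(series.pairs, series.fst_values)):
        model = fit_elastic_net(
            x.values[pair.train_idx], y.y[pair.train_idx],
            seed=int(seeds[k]), **fit_kwargs,
        )
        y_hat = predict_phenotypes(model, x.values[pair.target_idx])
        try:
            rho = predictive_correlation(y_hat, y.y[pair.target_idx])
        except UndefinedCorrelationError:
            continue
        points.append(DecayPoint(m=pair.m, fst=fst_val, rho=rho))
    return points


@dataclass
class DecayRun:
    points: list
    curve: object
    linear: object
    series: object
    pair0: SubsetPair


def estimate_decay(
    g: GenotypeMatrix,
    y: Phenotype,
    seed: int = 0,
    step: int | None = None,
    reps_per_m: int = 40,
    fst_stop: float = 0.005,
    n_target_required: int | None = None,
    span: float = 0.75,
    **fit_kwargs,
) -> DecayRun:
    """Clustering split, swap series and decay curve for one complete,
    QC'd genotype matrix with matched phenotypes."""
    x = standardize(g)
    pair0 = split_minimally_related(x, seed=seed)
    log.info("k-means split: n_TR=%d n_TA=%d", pair0.n_train, pair0.n_target)
    if n_target_required is not None and n_target_required < pair0.n_target:
        pair0 = rebalance(pair0, g, n_target_required)
        log.info("rebalanced to n_TR=%d n_TA=%d", pair0.n_train, pair0.n_target)
    series = generate_swap_series(
        x, g, pair0, step=step, reps_per_m=reps_per_m, fst_stop=fst_stop,
        seed=seed + 1,
    )
    log.info("swap schedule: %s", series.schedule)
    points = decay_points_from_series(x, y, series, seed=seed + 2, **fit_kwargs)
    curve = fit_decay_curve(points, span=span)
    linear = fit_linear(points)
    return DecayRun(points=points, curve=curve, linear=linear, series=series,
                    pair0=pair0)


def run_decay(config: dict) -> dict:
    """Config-driven decay-curve run; writes points/curve CSVs, a plot and a
    log to the output directory.  Returns the artifact paths."""
    outdir = Path(config.get("output_dir", "gpdecay_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir / "run.log")
    seed = int(config.get("seed", 0))
    g = read_genotypes(config["genotypes"], format=config.get("format", "csv"))
    pheno = read_phenotypes(config["phenotypes"])
    g = preprocess(
        g,
        maf_min=float(config.get("maf_min", 0.01)),
        missing_max=float(config.get("missing_max", 0.20)),
        r_max=float(config.get("r_max", 0.95)),
        seed=seed,
    )
    pheno = match_phenotype(g, pheno)
    fit_kwargs = dict(config.get("elastic_net", {}))
    run = estimate_decay(
        g,
        pheno,
        seed=seed,
        step=config.get("step"),
        reps_per_m=int(config.get("reps_per_m", 40)),
        fst_stop=float(config.get("fst_stop", 0.005)),
        n_target_required=config.get("n_target_required"),
        span=float(config.get("span", 0.75)),
        **fit_kwargs,
    )
    points_csv = outdir / "points.csv"
    curve_csv = outdir / "curve.csv"
    plot_path = outdir / "decay.png"
    points_to_csv(run.points, points_csv)
    decay_mod.curve_to_csv(run.curve, curve_csv)
    plot_decay(run.curve, run.linear, plot_path)
    with open(outdir / "linear.json", "w") as fh:
        json.dump(
            {
                "intercept": run.linear.intercept,
                "slope": run.linear.slope,
                "r_squared": run.linear.r_squared,
            },
            fh,
            indent=2,
        )
    log.info("decay run complete: %d points", len(run.points))
    return {
        "points": str(points_csv),
        "curve": str(curve_csv),
        "plot": str(plot_path),
        "linear": str(outdir / "linear.json"),
    }


def run_simulation(config: dict, which: str) -> dict:
    """Run the breeding or cross-population experiment on synthetic founders
    and overlay the reference points on the decay curve."""
    from .synthetic_data import two_population_fixture

    outdir = Path(config.get("output_dir", "gpdecay_sim"))
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir / "run.log")
    seed = int(config.get("seed", 0))
    n_markers = int(config.get("n_markers", 2000))
    fit_kwargs = dict(config.get("elastic_net", {}))
    fit_kwargs.setdefault("l1_ratios", (0.5, 1.0))
    fit_kwargs.setdefault("n_alphas", 25)
    fit_kwargs.setdefault("cv_runs", 1)
    fit_kwargs.setdefault("folds", 5)

    if which == "breeding":
        founders = two_population_fixture(
            float(config.get("founder_fst", 0.05)),
            sizes=tuple(config.get("founder_sizes", (100, 100))),
            n_markers=n_markers,
            seed=seed,
        )
        founders = apply_qc(founders, maf_min=0.01)
        trait = assign_trait(
            founders,
            n_causal=int(config.get("n_causal", 200)),
            h2=float(config.get("h2", 0.55)),
            seed=seed + 1,
        )
        pheno = sim_phenotype(founders, trait, seed=seed + 2)
        x = standardize(founders)
        model = fit_elastic_net(x.values, pheno.y, seed=seed + 3, **fit_kwargs)
        traj = run_selection_program(
            founders,
            trait,
            model,
            rounds=int(config.get("rounds", 10)),
            n_progeny=int(config.get("n_progeny", 200)),
            n_selected=int(config.get("n_selected", 20)),
            replicates=int(config.get("replicates", 100)),
            seed=seed + 4,
            scaler=x,
        )
        run = estimate_decay(
            founders,
            pheno,
            seed=seed + 5,
            step=config.get("step"),
            reps_per_m=int(config.get("reps_per_m", 40)),
            **fit_kwargs,
        )
        traj_csv = outdir / "trajectory.csv"
        with open(traj_csv, "w") as fh:
            fh.write("round,mean_fst,mean_rho\n")
            for r, (f, p) in enumerate(zip(traj.mean_fst, traj.mean_rho), 1):
                fh.write(f"{r},{f:.6f},{p:.6f}\n")
        refs = list(zip(traj.mean_fst, traj.mean_rho))
        plot_path = outdir / "overlay.png"
        plot_decay(run.curve, run.linear, plot_path, reference_points=refs,
                   title="breeding-program generations vs decay curve")
        points_to_csv(run.points, outdir / "points.csv")
        return {"trajectory": str(traj_csv), "plot": str(plot_path)}

    if which == "cross_population":
        from .synthetic_data import PopulationSpec, simulate_structured_population

        fsts = list(config.get("pop_fsts", (0.01, 0.05, 0.10)))
        sizes = list(config.get("pop_sizes", [100] * len(fsts)))
        spec = PopulationSpec(
            n_pops=len(fsts), sizes=sizes, fst_true=fsts, n_markers=n_markers
        )
        g = simulate_structured_population(spec, seed=seed)
        trait = assign_trait(
            g, n_causal=int(config.get("n_causal", 100)),
            h2=float(config.get("h2", 0.55)), seed=seed + 1,
        )
        records = cross_population_experiment(
            g, train_pop=str(config.get("train_pop", "pop0")), trait=trait,
            seed=seed + 2, **fit_kwargs,
        )
        targets_csv = outdir / "targets.csv"
        with open(targets_csv, "w") as fh:
            fh.write("population,fst,rho,ci_low,ci_high,n\n")
            for r in records:
                fh.write(
                    f"{r.label},{r.fst:.6f},{r.rho:.6f},"
                    f"{r.ci_low:.6f},{r.ci_high:.6f},{r.n_target}\n"
                )
        return {"targets": str(targets_csv)}

    raise GpdecayError(f"unknown simulation {which!r}")


def _setup_log(path: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(path)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
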