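"""Prediction scenarios, observed accuracy, and expected-vs-observed checks.

The harness mirrors the standard experiments for reliability criteria in
structured populations:

* S1 — one family predicted by another family (cross-with-cross),
* S2 — one family predicted by all other families (leave-one-cross-out),
* S3 — families predicted by a diverse panel, plus the pooled target set,
* OT1..OT4 — calibration sets of increasing size sampled (by the CD
  criteria, by mean relatedness, stratified, or at random) from the
  other families (OT1), from a panel to predict one family (OT2), from
  all families to predict all families (OT3), or from a panel to predict
  all families (OT4).

Expected accuracy is the CD-derived forecast (cdpop / cdallnam /
cdpop_mean); observed accuracy is the correlation between GEBV and
phenotypes of the target individuals divided by sqrt(h2) of the
predicted family, keeping the sign so that negative correlations remain
visible. In the S scenarios phenotypes are assumed available, so the
variance ratio comes from the calibration set's heritability (or REML);
in the OT scenarios phenotypes are not yet collected and lambda defaults
to 1 (h2 = 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cd_core import cd_criterion, crit_kin
from .gblup import MixedModelSpec, estimate_lambda_reml, lambda_from_h2, solve_gblup
from .genotypes import (
    GenotypeMatrix,
    KinshipMatrix,
    compute_allele_frequencies,
    vanraden_kinship,
)
from .optimizer import (
    CalibrationDesign,
    OptimizerConfig,
    exchange_optimize,
    greedy_crit_kin_start,
    sample_baseline,
)
from .simulator import (
    GeneticMap,
    SimulatedPopulation,
    realized_family_h2,
    simulate_ancestral_inbreds,
    simulate_founders,
    simulate_nam,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

S_SCENARIOS = ("S1", "S2", "S3")
OT_SCENARIOS = ("OT1", "OT2", "OT3", "OT4")

#: calibration-set sizes per optimization scenario when none are given
DEFAULT_SIZES = {
    "OT1": [10, 50, 150, 300, 500],
    "OT2": [10, 25, 50, 100, 200],
    "OT3": [50, 150, 300, 500],
    "OT4": [10, 25, 50, 100, 200],
}

DEFAULT_SAMPLERS = {
    "OT1": ["cdpop", "crit_kin", "random"],
    "OT2": ["cdpop", "crit_kin", "random"],
    "OT3": ["cdpop_mean", "cdallnam", "stratified_equal", "stratified_size", "random"],
    "OT4": ["cdpop_mean", "cdallnam", "random"],
}


def observed_accuracy(
    predictions: Sequence[float] | pd.Series,
    phenotypes: Sequence[float] | pd.Series,
    h2: float,
) -> float:
    """Observed prediction accuracy: Pearson correlation / sqrt(h2).

    Dividing by the square root of the predicted family's heritability
    rescales the GEBV-phenotype correlation to the genetic-value scale.
    The sign is preserved so that negative correlations stay negative,
    and values may exceed 1 through sampling noise.
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("predictions and phenotypes must be equal-length vectors (>= 3)")
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in predictions or phenotypes")
    return float(np.corrcoef(x, y)[0, 1] / np.sqrt(h2))


@dataclass
class PredictionDataset:
    """Everything a prediction scenario needs, independent of file formats.

    ``family_of`` labels the structured (NAM) individuals; ``panel_ids``
    lists the diverse-panel individuals usable as an external calibration
    pool. ``h2`` maps family label -> heritability and may carry the
    special keys ``"pooled"`` (whole target population) and ``"panel"``.
    """

    kinship: KinshipMatrix
    family_of: dict[str, str]
    phenotypes: pd.Series
    h2: dict[str, float]
    panel_ids: list[str] | None = None

    def families(self) -> dict[str, list[str]]:
        """Family -> member ids, both in kinship order."""
        out: dict[str, list[str]] = {}
        for ind in self.kinship.individual_ids:
            fam = self.family_of.get(ind)
            if fam is not None:
                out.setdefault(fam, []).append(ind)
        return out

    def nam_ids(self) -> list[str]:
        return [i for i in self.kinship.individual_ids if i in self.family_of]


@dataclass
class ScenarioConfig:
    """Settings of one scenario run.

    ``lambda_policy`` is ``from_h2_table`` (S default), ``fixed_1`` (OT
    default: lambda = 1, i.e. h2 = 0.5, for optimization before
    phenotyping) or ``reml``. The optimizer settings are deliberately
    smaller than the library defaults — scenario experiments run the
    exchange search many times, and a few hundred proposals per restart
    are enough at these pool sizes.
    """

    scenario: str
    calibration_sizes: list[int] | None = None
    n_random_reps: int = 20
    lambda_policy: str | None = None
    seed: int = 0
    predicted_families: list[str] | None = None
    samplers: list[str] | None = None
    optimizer_max_iterations: int = 400
    optimizer_patience: int = 120
    optimizer_restarts: int = 2

    def __post_init__(self) -> None:
        if self.scenario not in S_SCENARIOS + OT_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.lambda_policy is None:
            self.lambda_policy = (
                "from_h2_table" if self.scenario in S_SCENARIOS else "fixed_1"
            )
        if self.lambda_policy not in ("from_h2_table", "fixed_1", "reml"):
            raise ValueError(f"unknown lambda policy {self.lambda_policy!r}")
        if self.calibration_sizes is not None and any(
            s < 1 for s in self.calibration_sizes
        ):
            raise ValueError("calibration sizes must be positive")


# ---------------------------------------------------------------------------
# simulated study datasets
# ---------------------------------------------------------------------------


def simulate_prediction_dataset(
    family_sizes: Sequence[int] = (64, 99, 100, 66, 96, 104, 53, 94, 81, 84),
    n_panel: int = 0,
    h2: float = 0.5,
    n_ancestors: int = 4,
    n_chromosomes: int = 5,
    loci_per_chromosome: int = 60,
    chromosome_length_cm: float = 150.0,
    maf_low: float = 0.1,
    n_qtl: int | str = "all",
    freq_source: str = "all",
    seed: int = 0,
) -> tuple[PredictionDataset, SimulatedPopulation]:
    """Simulate a NAM design (plus optional panel) ready for scenarios.

    The default family sizes are unequal on purpose — real NAM designs
    have strongly varying family sizes (tens to low hundreds of DH lines
    per cross), and that variation is one driver of between-family
    differences in reliability. The central line, the donor parents and
    the optional panel are all inbreds bred from a small pool of
    ``n_ancestors`` ancestral founders, so family pairs range from
    closely related (donors sharing an ancestor) to unrelated beyond the
    central parent — the second driver of reliability differences in
    elite material. The panel contains the NAM parental lines plus
    further ancestral-cross inbreds. Heritabilities in the returned
    dataset are realized design-level values computed from the
    simulation ground truth.
    """
    ss = np.random.SeedSequence(seed)
    s_anc, s_par, s_nam, s_panel, s_phen = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    gmap = GeneticMap.uniform(n_chromosomes, loci_per_chromosome, chromosome_length_cm)
    n_fam = len(family_sizes)
    ancestors = simulate_founders(n_ancestors, gmap, maf_low=maf_low, seed=s_anc)
    parents = simulate_ancestral_inbreds(
        n_fam + 1, ancestors, gmap, seed=s_par, id_prefix="parent"
    )
    central = parents.values[0]
    donors = parents.subset(individuals=parents.individual_ids[1:])
    nam = simulate_nam(central, donors, list(family_sizes), gmap, seed=s_nam)
    ids = list(nam.genotypes.individual_ids)
    values = [nam.genotypes.values]
    panel_ids: list[str] | None = None
    if n_panel > 0:
        n_extra = max(0, n_panel - parents.n_individuals)
        extra = simulate_ancestral_inbreds(
            n_extra, ancestors, gmap, seed=s_panel, id_prefix="panel"
        ) if n_extra else None
        panel_ids = list(parents.individual_ids) + (
            list(extra.individual_ids) if extra is not None else []
        )
        ids = ids + panel_ids
        values.append(parents.values)
        if extra is not None:
            values.append(extra.values)
    combined = GenotypeMatrix(
        ids,
        list(gmap.locus_ids),
        np.vstack(values),
        family_of=dict(nam.genotypes.family_of),
    )
    pop = simulate_phenotypes(combined, h2=h2, n_qtl=n_qtl, seed=s_phen)
    if freq_source == "panel" and panel_ids:
        freqs = compute_allele_frequencies(combined, subset=panel_ids, source="panel")
    else:
        freqs = compute_allele_frequencies(combined, source="all")
    kinship = vanraden_kinship(combined, freqs)
    h2_map = realized_family_h2(pop)
    if panel_ids:
        v = float(pop.true_breeding_values.loc[panel_ids].var(ddof=1))
        h2_map["panel"] = v / (v + pop.sigma_e2) if (v + pop.sigma_e2) > 0 else 1.0
    dataset = PredictionDataset(
        kinship=kinship,
        family_of=dict(nam.genotypes.family_of),
        phenotypes=pop.phenotypes,
        h2=h2_map,
        panel_ids=panel_ids,
    )
    return dataset, pop


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------


def _lambda_for(
    data: PredictionDataset,
    policy: str,
    calibration_ids: Sequence[str],
    cal_families: Sequence[str] | None,
) -> float:
    if policy == "fixed_1":
        return 1.0
    if policy == "reml":
        lam, _, _ = estimate_lambda_reml(
            data.phenotypes.loc[list(calibration_ids)],
            data.kinship.subset(list(calibration_ids)),
        )
        return lam
    # from_h2_table
    if cal_families is None:  # panel calibration
        h2 = data.h2.get("panel", data.h2.get("pooled"))
        if h2 is None:
            raise ValueError("h2 table has neither 'panel' nor 'pooled' entry")
    elif len(cal_families) == 1:
        h2 = data.h2[cal_families[0]]
    elif "pooled" in data.h2:
        h2 = data.h2["pooled"]
    else:
        h2 = float(np.mean([data.h2[f] for f in cal_families]))
        logger.warning(
            "no pooled h2 available for a multi-family calibration set; "
            "using the unweighted mean of the family h2 values"
        )
    return lambda_from_h2(h2)


def _gblup_predictions(
    data: PredictionDataset,
    calibration_ids: Sequence[str],
    target_ids: Sequence[str],
    lam: float,
) -> pd.Series:
    wanted = set(calibration_ids) | set(target_ids)
    model_ids = [i for i in data.kinship.individual_ids if i in wanted]
    spec = MixedModelSpec(list(calibration_ids), model_ids, lam)
    sol = solve_gblup(data.phenotypes, data.kinship, spec)
    return sol.u_hat.loc[list(target_ids)]


def _accuracy(
    data: PredictionDataset,
    predictions: pd.Series,
    target_ids: Sequence[str],
    h2: float,
) -> float:
    return observed_accuracy(
        predictions.loc[list(target_ids)],
        data.phenotypes.loc[list(target_ids)],
        h2,
    )


def run_scenario(data: PredictionDataset, config: ScenarioConfig) -> pd.DataFrame:
    """Run one scenario end to end and return the per-cell report table.

    Columns: scenario, predicted_family, calibration, size, sampler,
    replicate, criterion, criterion_value, expected_accuracy,
    observed_accuracy, scope, lam. ``scope`` is ``within`` for
    per-family accuracies and ``global`` for the pooled target set.
    """
    if config.scenario in S_SCENARIOS:
        rows = _run_s(data, config)
    else:
        rows = _run_ot(data, config)
    return pd.DataFrame(rows)


def _usable_families(data: PredictionDataset) -> dict[str, list[str]]:
    fams = data.families()
    out = {}
    for fam, ids in fams.items():
        if len(ids) < 2:
            logger.warning("family %s has fewer than 2 members; skipped", fam)
            continue
        out[fam] = ids
    return out


def _row(**kw) -> dict:
    base = dict(
        scenario=None, predicted_family=None, calibration=None, size=None,
        sampler=None, replicate=0, criterion=None, criterion_value=np.nan,
        expected_accuracy=np.nan, observed_accuracy=np.nan, scope="within",
        lam=np.nan,
    )
    base.update(kw)
    return base


def _run_s(data: PredictionDataset, config: ScenarioConfig) -> list[dict]:
    fams = _usable_families(data)
    rows: list[dict] = []
    if config.scenario == "S1":
        for cal_f, cal_ids in fams.items():
            lam = _lambda_for(data, config.lambda_policy, cal_ids, [cal_f])
            for pred_f, pred_ids in fams.items():
                if pred_f == cal_f:
                    continue
                expected = cd_criterion(
                    data.kinship, cal_ids, pred_ids, "cdpop", lam
                ).aggregate
                preds = _gblup_predictions(data, cal_ids, pred_ids, lam)
                obs = _accuracy(data, preds, pred_ids, data.h2[pred_f])
                rows.append(_row(
                    scenario="S1", predicted_family=pred_f, calibration=cal_f,
                    size=len(cal_ids), criterion="cdpop",
                    criterion_value=expected, expected_accuracy=expected,
                    observed_accuracy=obs, lam=lam,
                ))
        return rows
    if config.scenario == "S2":
        for pred_f, pred_ids in fams.items():
            cal_families = [f for f in fams if f != pred_f]
            cal_ids = [i for f in cal_families for i in fams[f]]
            lam = _lambda_for(data, config.lambda_policy, cal_ids, cal_families)
            expected = cd_criterion(
                data.kinship, cal_ids, pred_ids, "cdpop", lam
            ).aggregate
            preds = _gblup_predictions(data, cal_ids, pred_ids, lam)
            obs = _accuracy(data, preds, pred_ids, data.h2[pred_f])
            rows.append(_row(
                scenario="S2", predicted_family=pred_f, calibration="all-others",
                size=len(cal_ids), criterion="cdpop", criterion_value=expected,
                expected_accuracy=expected, observed_accuracy=obs, lam=lam,
            ))
        return rows
    # S3
    if not data.panel_ids:
        raise ValueError("scenario S3 requires a panel calibration pool")
    cal_ids = list(data.panel_ids)
    lam = _lambda_for(data, config.lambda_policy, cal_ids, None)
    nam = data.nam_ids()
    preds_all = _gblup_predictions(data, cal_ids, nam, lam)
    for pred_f, pred_ids in fams.items():
        expected = cd_criterion(
            data.kinship, cal_ids, pred_ids, "cdpop", lam
        ).aggregate
        obs = _accuracy(data, preds_all, pred_ids, data.h2[pred_f])
        rows.append(_row(
            scenario="S3", predicted_family=pred_f, calibration="panel",
            size=len(cal_ids), criterion="cdpop", criterion_value=expected,
            expected_accuracy=expected, observed_accuracy=obs, lam=lam,
        ))
    expected_all = cd_criterion(data.kinship, cal_ids, nam, "cdallnam", lam).aggregate
    h2_pool = data.h2.get("pooled", float(np.mean(list(data.h2.values()))))
    obs_all = _accuracy(data, preds_all, nam, h2_pool)
    rows.append(_row(
        scenario="S3", predicted_family="ALL", calibration="panel",
        size=len(cal_ids), criterion="cdallnam", criterion_value=expected_all,
        expected_accuracy=expected_all, observed_accuracy=obs_all,
        scope="global", lam=lam,
    ))
    return rows


def _make_calibration(
    data: PredictionDataset,
    sampler: str,
    pool: list[str],
    size: int,
    target_ids: list[str],
    targets_map: Mapping[str, list[str]] | None,
    lam: float,
    config: ScenarioConfig,
    seed: int,
) -> CalibrationDesign:
    K = data.kinship
    if sampler == "random":
        return sample_baseline(pool, size, "random", seed=seed)
    if sampler in ("stratified_equal", "stratified_size"):
        return sample_baseline(
            pool, size, sampler, family_of=data.family_of, seed=seed
        )
    if sampler == "crit_kin":
        ids = greedy_crit_kin_start(K, pool, target_ids, size)
        return CalibrationDesign(
            ids, "crit_kin", crit_kin(K, ids, target_ids), seed=seed
        )
    if sampler in ("cdpop", "cdallnam", "cdpop_mean"):
        targets = targets_map if sampler == "cdpop_mean" else target_ids
        crit = lambda s: cd_criterion(K, s, targets, sampler, lam).aggregate
        cfg = OptimizerConfig(
            size=size,
            max_iterations=config.optimizer_max_iterations,
            patience=config.optimizer_patience,
            restarts=config.optimizer_restarts,
            seed=seed,
        )
        return exchange_optimize(pool, crit, cfg, criterion_name=sampler)
    raise ValueError(f"unknown sampler {sampler!r}")


def _run_ot(data: PredictionDataset, config: ScenarioConfig) -> list[dict]:
    scenario = config.scenario
    fams = _usable_families(data)
    nam = data.nam_ids()
    sizes = config.calibration_sizes or DEFAULT_SIZES[scenario]
    samplers = config.samplers or DEFAULT_SAMPLERS[scenario]
    if scenario in ("OT2", "OT4") and not data.panel_ids:
        raise ValueError(f"scenario {scenario} requires a panel calibration pool")
    rows: list[dict] = []

    if scenario in ("OT1", "OT2"):
        predicted = config.predicted_families or list(fams)
        for fi, pred_f in enumerate(predicted):
            target_ids = fams[pred_f]
            pool = (
                [i for i in nam if data.family_of[i] != pred_f]
                if scenario == "OT1"
                else list(data.panel_ids)
            )
            for si, size in enumerate(sizes):
                if size >= len(pool):
                    logger.warning(
                        "size %d >= pool of %d for family %s; skipped",
                        size, len(pool), pred_f,
                    )
                    continue
                lam = (
                    1.0
                    if config.lambda_policy == "fixed_1"
                    else _lambda_for(data, config.lambda_policy, pool, None)
                )
                for mi, sampler in enumerate(samplers):
                    for rep in range(config.n_random_reps):
                        seed = int(
                            np.random.SeedSequence(
                                [config.seed, fi, si, mi, rep]
                            ).generate_state(1)[0] % (2**31)
                        )
                        design = _make_calibration(
                            data, sampler, pool, size, target_ids, None,
                            lam, config, seed,
                        )
                        preds = _gblup_predictions(
                            data, design.selected_ids, target_ids, lam
                        )
                        obs = _accuracy(data, preds, target_ids, data.h2[pred_f])
                        rows.append(_row(
                            scenario=scenario, predicted_family=pred_f,
                            calibration=sampler, size=size, sampler=sampler,
                            replicate=rep, criterion=design.criterion_name,
                            criterion_value=design.criterion_value,
                            observed_accuracy=obs, lam=lam,
                        ))
        return rows

    # OT3 / OT4: all families predicted jointly
    target_ids = [i for ids in fams.values() for i in ids]
    targets_map = fams
    pool = list(target_ids) if scenario == "OT3" else list(data.panel_ids)
    h2_pool = data.h2.get("pooled", float(np.mean(list(data.h2.values()))))
    for si, size in enumerate(sizes):
        if size >= len(pool):
            logger.warning("size %d >= pool of %d; skipped", size, len(pool))
            continue
        for mi, sampler in enumerate(samplers):
            for rep in range(config.n_random_reps):
                seed = int(
                    np.random.SeedSequence(
                        [config.seed, si, mi, rep]
                    ).generate_state(1)[0] % (2**31)
                )
                lam = 1.0 if config.lambda_policy == "fixed_1" else _lambda_for(
                    data, config.lambda_policy, pool, None
                )
                design = _make_calibration(
                    data, sampler, pool, size, target_ids, targets_map,
                    lam, config, seed,
                )
                preds = _gblup_predictions(
                    data, design.selected_ids, target_ids, lam
                )
                for pred_f, pred_ids in fams.items():
                    obs = _accuracy(data, preds, pred_ids, data.h2[pred_f])
                    rows.append(_row(
                        scenario=scenario, predicted_family=pred_f,
                        calibration=sampler, size=size, sampler=sampler,
                        replicate=rep, criterion=design.criterion_name,
                        criterion_value=design.criterion_value,
                        observed_accuracy=obs, lam=lam,
                    ))
                obs_g = _accuracy(data, preds, target_ids, h2_pool)
                rows.append(_row(
                    scenario=scenario, predicted_family="ALL",
                    calibration=sampler, size=size, sampler=sampler,
                    replicate=rep, criterion=design.criterion_name,
                    criterion_value=design.criterion_value,
                    observed_accuracy=obs_g, scope="global", lam=lam,
                ))
    return rows


# ---------------------------------------------------------------------------
# expected vs observed
# ---------------------------------------------------------------------------


def expected_vs_observed_summary(
    report: pd.DataFrame,
    group_col: str = "predicted_family",
    expected_col: str = "expected_accuracy",
    observed_col: str = "observed_accuracy",
) -> pd.DataFrame:
    """Correlation and regression of observed on expected accuracy.

    One row per group (predicted family) with at least 3 complete pairs
    and non-degenerate variance, plus a ``pooled`` row over all pairs.
    """
    usable = report[[group_col, expected_col, observed_col]].dropna()
    rows = []

    def _summarize(label: str, block: pd.DataFrame) -> None:
        x = block[expected_col].to_numpy(float)
        y = block[observed_col].to_numpy(float)
        if len(x) < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
            logger.warning("group %s skipped (too few pairs or no variance)", label)
            return
        fit = stats.linregress(x, y)
        rows.append(dict(
            group=label, n_pairs=len(x),
            correlation=float(np.corrcoef(x, y)[0, 1]),
            slope=float(fit.slope), intercept=float(fit.intercept),
        ))

    for label, block in usable.groupby(group_col, sort=True):
        _summarize(str(label), block)
    _summarize("pooled", usable)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation benchmarks (directional reproduction of the study findings)
# ---------------------------------------------------------------------------


def ot1_benchmark(
    seed: int = 0,
    n_families: int = 5,
    family_size: int = 150,
    sizes: Sequence[int] = (30, 60),
    n_replicates: int = 10,
    n_random_sets: int = 5,
    loci_per_chromosome: int = 60,
    n_chromosomes: int = 5,
) -> dict:
    """CDpop-optimized vs random calibration sets on simulated NAMs (OT1).

    Each family is predicted in turn from calibration sets sampled in
    the other families, and observed accuracies are averaged over the
    predicted families (the standard way OT1 results are reported).
    Each replicate is an independent simulated design and trait; per
    replicate, the family-averaged accuracy of the CDpop-optimized sets
    (one exchange run per family and size) is averaged over the
    calibration sizes and compared with the corresponding average over
    ``n_random_sets`` size-matched random sets. ``win_fraction`` is the
    share of replicates where the optimized sets do at least as well.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data, _ = simulate_prediction_dataset(
            family_sizes=[family_size] * n_families,
            n_chromosomes=n_chromosomes,
            loci_per_chromosome=loci_per_chromosome,
            seed=rep_seed,
        )
        config = ScenarioConfig(scenario="OT1", seed=rep_seed)
        fams = data.families()
        for fi, target_family in enumerate(sorted(fams)):
            target_ids = fams[target_family]
            pool = [
                i for i in data.nam_ids() if data.family_of[i] != target_family
            ]
            h2_t = data.h2[target_family]
            for si, size in enumerate(sizes):
                opt = _make_calibration(
                    data, "cdpop", pool, size, target_ids, None, 1.0, config,
                    seed=int(np.random.SeedSequence(
                        [rep_seed, fi, si]
                    ).generate_state(1)[0] % (2**31)),
                )
                preds = _gblup_predictions(data, opt.selected_ids, target_ids, 1.0)
                rows.append(dict(
                    replicate=rep, family=target_family, size=size,
                    sampler="cdpop", criterion_value=opt.criterion_value,
                    observed_accuracy=_accuracy(data, preds, target_ids, h2_t),
                ))
                for r in range(n_random_sets):
                    rnd = sample_baseline(
                        pool, size, "random",
                        seed=int(np.random.SeedSequence(
                            [rep_seed, fi, si, r]
                        ).generate_state(1)[0] % (2**31)),
                    )
                    preds = _gblup_predictions(data, rnd.selected_ids, target_ids, 1.0)
                    rows.append(dict(
                        replicate=rep, family=target_family, size=size,
                        sampler="random", criterion_value=np.nan,
                        observed_accuracy=_accuracy(data, preds, target_ids, h2_t),
                    ))
    report = pd.DataFrame(rows)
    per_rep = report.pivot_table(
        index="replicate", columns="sampler", values="observed_accuracy",
        aggfunc="mean",
    )
    wins = per_rep["cdpop"] >= per_rep["random"]
    return {
        "win_fraction": float(wins.mean()),
        "n_replicates": int(len(per_rep)),
        "mean_accuracy_cdpop": float(per_rep["cdpop"].mean()),
        "mean_accuracy_random": float(per_rep["random"].mean()),
        "report": report,
    }


def s1_benchmark(
    seed: int = 0,
    family_sizes: Sequence[int] = (64, 99, 100, 66, 96, 104, 53, 94, 81, 84),
    n_replicates: int = 20,
    loci_per_chromosome: int = 60,
    n_chromosomes: int = 5,
) -> dict:
    """Does the CDpop forecast rank S1 prediction accuracies correctly?

    Each replicate simulates a fresh NAM design with unequal family
    sizes, runs the cross-with-cross scenario over all ordered family
    pairs, and records the Spearman correlation between expected (CDpop)
    and observed accuracy. Returns the fraction of replicates with a
    positive rank correlation.
    """
    spearman = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data, _ = simulate_prediction_dataset(
            family_sizes=list(family_sizes),
            n_chromosomes=n_chromosomes,
            loci_per_chromosome=loci_per_chromosome,
            seed=rep_seed,
        )
        report = run_scenario(
            data, ScenarioConfig(scenario="S1", seed=rep_seed)
        )
        rho = stats.spearmanr(
            report["expected_accuracy"], report["observed_accuracy"]
        ).statistic
        spearman.append(float(rho))
    spearman = np.asarray(spearman)
    return {
        "positive_fraction": float(np.mean(spearman > 0)),
        "spearman": spearman,
        "n_pairs": len(family_sizes) * (len(family_sizes) - 1),
        "n_replicates": int(n_replicates),
    }
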