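"""Power / coverage / type-I-error benchmark across methods and conditions.

For each condition (source density x target density x images per patient)
and replicate, a hierarchical study is generated twice — once with the
true bump SIC (power, coverage) and once with all interaction
coefficients forced to zero (type-I error) — and every method makes an
image-level detection call on the 0-75 um range:

* ``shade_hier``  — simultaneous band of the image-level SIC from the
  hierarchical fit excludes zero somewhere;
* ``shade_flat``  — same rule from independent per-image fits;
* ``gcross`` / ``kcross`` — global CSR envelope test rejects.

Power is the per-replicate proportion of images detected on the
alternative study; type-I error the same proportion on the null study;
coverage (SHADE only) the proportion of images whose simultaneous band
contains the true image-level SIC at every grid point of the interval.
The table reports the median of the per-replicate rates per condition.
All randomness derives from a master seed through per-(condition,
replicate) seed sequences, so results are independent of execution order
and replicates can be recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import EnvelopeResult, envelope_test
from .model import FlatSICModel, SHADEModel
from .summaries import CredibleBand, detect_interaction
from .simulate import SimulationConfig, simulate_study, true_sic

__all__ = ["BenchmarkTable", "score_replicate", "run_benchmark"]

METHODS = ("shade_hier", "shade_flat", "gcross", "kcross")

_FIT_DEFAULTS = {"chains": 2, "warmup": 400, "draws": 400}


@dataclass
class BenchmarkTable:
    """Aggregated benchmark results.

    ``summary``: one row per condition x method with median power,
    coverage and type-I error.  ``replicates``: one row per condition x
    method x replicate with the underlying rates.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame

    def __post_init__(self):
        rates = self.summary[["power", "coverage", "type1"]].to_numpy(dtype=float)
        finite = np.isfinite(rates)
        if finite.any() and not ((rates[finite] >= 0) & (rates[finite] <= 1)).all():
            raise ValueError("rates must lie in [0, 1]")

    def to_csv(self, summary_path, replicates_path=None):
        self.summary.to_csv(summary_path, index=False)
        if replicates_path is not None:
            self.replicates.to_csv(replicates_path, index=False)


def score_replicate(output, truth, interval=(0.0, 75.0), unit=None,
                    source=None, basis=None) -> dict:
    """Score one image-level method output against the generating truth.

    ``output`` may be an EnvelopeResult (detection = rejection flag), a
    CredibleBand (detection = band excludes zero in the interval; coverage
    = band contains the true image SIC everywhere in the interval), or a
    dict already containing a ``detected`` flag.  ``type1_flag`` is set
    when a detection occurs on a null replicate.
    """
    covered = None
    if isinstance(output, EnvelopeResult):
        detected = bool(output.rejected) and output.testable
    elif isinstance(output, CredibleBand):
        detected = detect_interaction(output, interval)["detected"]
        if truth is not None and unit is not None:
            grid = output.grid
            mask = (grid >= interval[0]) & (grid <= interval[1])
            truth_curve = true_sic(truth, basis, grid[mask], level="image",
                                   unit=unit, source=source)
            covered = bool(np.all((truth_curve >= output.lower[mask])
                                  & (truth_curve <= output.upper[mask])))
    elif isinstance(output, dict) and "detected" in output:
        detected = bool(output["detected"])
        covered = output.get("covered")
    else:
        raise TypeError(f"cannot score output of type {type(output).__name__}")
    is_null = bool(truth["null"]) if truth is not None else False
    return {"detected": detected, "covered": covered,
            "type1_flag": bool(detected and is_null)}


def _condition_seed(master_seed, ci, rep, arm):
    ss = np.random.SeedSequence((master_seed, ci, rep, arm))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _shade_scores(results, truth, interval, basis, source):
    """Image-level detection/coverage flags from a fitted study."""
    out = []
    for m in results.model.image_ids:
        band = results.credible_band(
            "image", m, source,
            grid=np.arange(interval[0], interval[1] + 0.5, 1.0),
            reporting=False)
        out.append(score_replicate(band, truth, interval, unit=m,
                                   source=source, basis=basis))
    return out


def run_benchmark(conditions, replicates=10, methods=METHODS, master_seed=0,
                  interval=(0.0, 75.0), fit_kwargs=None, null_only=False,
                  progress=False) -> BenchmarkTable:
    """Run the full simulation benchmark.

    Parameters
    ----------
    conditions : list of dict
        Each dict overrides :class:`SimulationConfig` fields, e.g.
        ``{"expected_source": 150, "expected_target": 15,
        "images_per_patient": 2, "n_patients": 10}``.
    replicates : int
        Studies per condition and arm (alternative / null).
    methods : subset of {"shade_hier", "shade_flat", "gcross", "kcross"}
    null_only : bool
        Skip the alternative arm; the power column then repeats the
        type-I rates by construction.
    fit_kwargs : dict
        Passed to the HMC fits (chains / warmup / draws / seed handling
        is internal).

    Individual replicate failures are recorded (NaN rates) rather than
    fatal.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    fit_kwargs = {**_FIT_DEFAULTS, **(fit_kwargs or {})}
    rep_rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(replicates):
            arms = {"null": True} if null_only else {"alt": False, "null": True}
            arm_scores = {}
            for ai, (arm, is_null) in enumerate(arms.items()):
                cfg = SimulationConfig(
                    seed=_condition_seed(master_seed, ci, rep, ai), **cond)
                try:
                    arm_scores[arm] = _run_arm(
                        cfg, is_null, methods, interval, fit_kwargs,
                        seed=_condition_seed(master_seed, ci, rep, 10 + ai))
                except Exception as exc:  # replicate failure is not fatal
                    arm_scores[arm] = {"error": repr(exc)}
            if null_only:
                arm_scores["alt"] = arm_scores["null"]
            for method in methods:
                row = {"condition": ci, "replicate": rep, "method": method}
                row.update(cond)
                alt = arm_scores["alt"].get(method)
                nul = arm_scores["null"].get(method)
                row["power"] = _rate(alt, "detected")
                row["coverage"] = _rate(alt, "covered")
                row["type1"] = _rate(nul, "type1_flag")
                row["error"] = (arm_scores["alt"].get("error")
                                or arm_scores["null"].get("error"))
                rep_rows.append(row)
            if progress:
                print(f"condition {ci} replicate {rep} done")
    reps = pd.DataFrame(rep_rows)
    summary = (
        reps.groupby(["condition", "method"], as_index=False)
        .agg(power=("power", "median"), coverage=("coverage", "median"),
             type1=("type1", "median"), n_replicates=("replicate", "count"))
    )
    cond_df = pd.DataFrame([{**{"condition": i}, **c}
                            for i, c in enumerate(conditions)])
    summary = summary.merge(cond_df, on="condition", how="left")
    return BenchmarkTable(summary=summary, replicates=reps)


def _rate(scores, key):
    if not isinstance(scores, list) or not scores:
        return np.nan
    vals = [s[key] for s in scores if s.get(key) is not None]
    return float(np.mean(vals)) if vals else np.nan


def _run_arm(cfg, is_null, methods, interval, fit_kwargs, seed):
    patterns, hierarchy, truth = simulate_study(cfg, null=is_null)
    source = cfg.source_labels[0]
    target = cfg.target_label
    basis = cfg.basis
    scores = {}
    need_designs = {"shade_hier", "shade_flat"} & set(methods)
    model = None
    if need_designs:
        model = SHADEModel.from_patterns(patterns, hierarchy, target,
                                         cfg.source_labels, basis=basis,
                                         seed=seed)
    if "shade_hier" in methods:
        res = model.fit(seed=seed + 1, **fit_kwargs)
        scores["shade_hier"] = _shade_scores(res, truth, interval, basis, source)
    if "shade_flat" in methods:
        flat_scores = []
        for i, ds in enumerate(model.datasets):
            fres = FlatSICModel(ds, basis, priors=model.priors).fit(
                seed=seed + 2 + i, chains=fit_kwargs.get("chains", 2),
                warmup=fit_kwargs.get("warmup", 400),
                draws=fit_kwargs.get("draws", 400))
            band = fres.credible_band(
                source, grid=np.arange(interval[0], interval[1] + 0.5, 1.0))
            flat_scores.append(
                score_replicate(band, truth, interval, unit=ds.image_id,
                                source=source, basis=basis))
        scores["shade_flat"] = flat_scores
    for stat in ("gcross", "kcross"):
        if stat in methods:
            stat_scores = []
            for i, pat in enumerate(patterns):
                env = envelope_test(pat, from_label=source, to_label=target,
                                    statistic=stat, n_sim=99,
                                    r=np.linspace(0.0, interval[1], 51),
                                    seed=seed + 1000 + i)
                stat_scores.append(score_replicate(env, truth, interval))
            scores[stat] = stat_scores
    return scores
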