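"""Config-driven orchestration: generate -> prep -> curves -> observables ->
inference -> decoding -> shapley, with seeds, logging and report bundles.

A run is described by a single YAML config (all defaults follow the study
protocol: 1000 permutations, 1000 bootstrap resamples, 0.95 quantile,
z > 2 / sigma < 0.15 / range > 0.1 selection, 5-fold CV with the stated
C and gamma grids, early windows maxima [1,5] / area [0,5] and late
windows [5,9] / [5,9]).  Every stage seed is derived from the run seed and
recorded in the output manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curves as curves_mod
from . import decoding as dec
from . import inference as inf
from . import observables as obs
from . import prep, shapley, simulate

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]

log = logging.getLogger("evlock")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


# ---------------------------------------------------------------------------
# config schema


@dataclass
class StageWindows:
    maxima: tuple[float, float]
    area: tuple[float, float]


@dataclass
class WindowsConfig:
    early: StageWindows = field(
        default_factory=lambda: StageWindows((1.0, 5.0), (0.0, 5.0))
    )
    late: StageWindows = field(
        default_factory=lambda: StageWindows((5.0, 9.0), (5.0, 9.0))
    )


@dataclass
class InferenceConfig:
    n_perm: int = 1000
    n_boot: int = 1000
    quantile: float = 0.95
    z_min: float = 2.0
    sigma_max: float = 0.15
    range_min: float = 0.1
    min_region_size: int = 10


@dataclass
class DecodingConfig:
    k: int = 5
    c_grid: tuple = dec.C_GRID
    gamma_grid: tuple = dec.GAMMA_GRID
    models: tuple = ("logreg",)
    tune: str = "nested"
    per_tr: bool = True


@dataclass
class ShapleyConfig:
    enabled: bool = True
    keep_fraction: float = 0.15
    n_estimators: int = 300


@dataclass
class NoiseConfig:
    ar1_coeff: float = 0.3
    white_sd: float = 1.0
    amp_jitter_sigma: float = 0.1


@dataclass
class DataConfig:
    source: str = "synthetic"
    tr_seconds: float = 1.8
    n_regions: int = 718
    n_subjects: int = 65
    n_sessions: int = 2
    n_trials_per_class: dict = field(
        default_factory=lambda: dict(simulate.STUDY_TRIAL_COUNTS)
    )
    lock_to_tr: bool = False
    # [lo, hi] or [lo, hi, mean] seconds; None keeps the task default
    iti_seconds: list | None = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    # each effect overrides the response template of one (region, class)
    effects: list = field(default_factory=list)
    session_files: list = field(default_factory=list)
    event_files: list = field(default_factory=list)


@dataclass
class RunConfig:
    seed: int = 0
    contrasts: list = field(
        default_factory=lambda: [["POScorr", "LURfalse"], ["NEGcorr", "LURcorr"]]
    )
    windows: WindowsConfig = field(default_factory=WindowsConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    shapley: ShapleyConfig = field(default_factory=ShapleyConfig)
    data: DataConfig = field(default_factory=DataConfig)


_NESTED = {
    "windows": WindowsConfig,
    "inference": InferenceConfig,
    "decoding": DecodingConfig,
    "shapley": ShapleyConfig,
    "data": DataConfig,
    "noise": NoiseConfig,
    "early": StageWindows,
    "late": StageWindows,
}


def _build(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key {path}{sorted(unknown)[0]!r}")
    kwargs = {}
    for name, value in raw.items():
        sub = _NESTED.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}{name}.")
        elif name in ("maxima", "area") and cls is StageWindows:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from None


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def validate_config(raw_text: str | dict | None) -> RunConfig:
    """Parse config text (YAML), fill defaults, reject unknown keys and
    out-of-range values with the path of the offending key."""
    if raw_text is None or (isinstance(raw_text, str) and not raw_text.strip()):
        data = {}
    elif isinstance(raw_text, dict):
        data = raw_text
    else:
        data = yaml.safe_load(raw_text)
        if data is None:
            data = {}
    cfg = _build(RunConfig, data, "")

    _check(0 < cfg.inference.quantile < 1,
           f"inference.quantile: {cfg.inference.quantile} not in (0, 1)")
    _check(cfg.inference.n_perm >= 100, "inference.n_perm: must be >= 100")
    _check(cfg.inference.n_boot >= 2, "inference.n_boot: must be >= 2")
    _check(0 < cfg.shapley.keep_fraction <= 1,
           f"shapley.keep_fraction: {cfg.shapley.keep_fraction} not in (0, 1]")
    _check(cfg.decoding.k >= 2, "decoding.k: must be >= 2")
    _check(cfg.data.source in ("synthetic", "files"),
           f"data.source: {cfg.data.source!r} not 'synthetic' or 'files'")
    for stage_name in ("early", "late"):
        sw = getattr(cfg.windows, stage_name)
        for win_name in ("maxima", "area"):
            lo, hi = getattr(sw, win_name)
            _check(-2.0 <= lo < hi <= 9.0,
                   f"windows.{stage_name}.{win_name}: [{lo}, {hi}] "
                   "must be increasing within [-2, 9]")
    known_classes = set(cfg.data.n_trials_per_class)
    if "contrasts" not in data:
        # default contrasts track whatever classes the data actually has
        cfg.contrasts = [
            pair for pair in cfg.contrasts if set(pair) <= known_classes
        ]
        _check(bool(cfg.contrasts),
               "data.n_trials_per_class: no default contrast pair is available "
               "for these classes; set `contrasts` explicitly")
    for pair in cfg.contrasts:
        _check(len(pair) == 2 and set(pair) <= known_classes,
               f"contrasts: {pair} is not a pair of known classes")
    return cfg


# ---------------------------------------------------------------------------
# data realization


def _templates_from_effects(design: simulate.TaskDesign, effects: list):
    book = simulate.null_templates(design)
    for eff in effects:
        eff = dict(eff)
        rid = eff.pop("region")
        cls = eff.pop("event_class")
        if rid not in book:
            raise ConfigError(f"data.effects: unknown region {rid!r}")
        if cls not in book[rid]:
            raise ConfigError(f"data.effects: unknown class {cls!r}")
        book[rid][cls] = replace(book[rid][cls], **eff)
    return book


def _load_sessions(data: DataConfig):
    sessions = [
        prep.ParcellatedTimeSeries.from_tsv(p, tr_seconds=data.tr_seconds)
        for p in data.session_files
    ]
    events = [
        prep.EventTable.from_tsv(p, tr_seconds=data.tr_seconds)
        for p in data.event_files
    ]
    if len(sessions) != len(events):
        raise ConfigError("data: session_files and event_files must pair up")
    return sessions, events


def design_from_config(data: DataConfig, seed: int) -> simulate.TaskDesign:
    kwargs = {}
    if data.iti_seconds is not None:
        if not 2 <= len(data.iti_seconds) <= 3:
            raise ConfigError("data.iti_seconds: expected [lo, hi] or [lo, hi, mean]")
        kwargs["iti_seconds"] = simulate.IntervalSpec(*data.iti_seconds)
    return simulate.TaskDesign(
        tr_seconds=data.tr_seconds,
        n_trials_per_class=dict(data.n_trials_per_class),
        n_subjects=data.n_subjects,
        n_sessions=data.n_sessions,
        n_regions=data.n_regions,
        lock_to_tr=data.lock_to_tr,
        rng_seed=seed,
        **kwargs,
    )


def prepare_trials(cfg: RunConfig, seed: int):
    """Simulate (or load) sessions and run the fixed preparation order."""
    if cfg.data.source == "synthetic":
        design = design_from_config(cfg.data, seed)
        noise = simulate.NoiseSpec(**asdict(cfg.data.noise))
        templates = _templates_from_effects(design, cfg.data.effects)
        dataset = simulate.simulate_dataset(design, templates, noise)
        sessions, events = dataset.sessions, dataset.events
    else:
        sessions, events = _load_sessions(cfg.data)

    normalized = [
        prep.ParcellatedTimeSeries(
            subject_id=s.subject_id, session_id=s.session_id,
            region_ids=s.region_ids, tr_seconds=s.tr_seconds,
            values=prep.normalize_within_session(s.values),
        )
        for s in sessions
    ]
    standardized = prep.standardize_across_dataset(normalized)
    tensor, dropped = prep.extract_dataset(standardized, events)
    return tensor, dropped


# ---------------------------------------------------------------------------
# stages


def _analysis_stage(cfg, tensor, contrast, stage_name, seed, out, man):
    """One contrast/stage: relevance screen plus both edge-delay tables.

    The leading and trailing delays both refer to the stage's in-window
    peak (its rising and falling side), each filtered by the same four
    criteria."""
    sw = getattr(cfg.windows, stage_name)
    a, b = contrast
    curves_a = curves_mod.class_mean_curves(tensor, a)
    curves_b = curves_mod.class_mean_curves(tensor, b)
    pairs = {rid: (curves_a[rid], curves_b[rid]) for rid in tensor.region_ids}

    perm = inf.permutation_critical_value(
        tensor, (a, b), sw.area,
        n_perm=cfg.inference.n_perm, quantile=cfg.inference.quantile, seed=seed,
    )
    tag = f"{a}-{b}_{stage_name}"
    n_delay_selected = {}
    area_table = None
    for edge in ("leading", "trailing"):
        criteria = inf.SelectionCriteria(
            z_min=cfg.inference.z_min,
            sigma_max=cfg.inference.sigma_max,
            range_min=cfg.inference.range_min,
            maxima_window=sw.maxima,
            area_window=sw.area,
            edge=edge,
            min_region_size=cfg.inference.min_region_size,
        )
        if area_table is None:  # relevance screen is edge-independent
            area_table = inf.select_area_regions(
                pairs, perm.critical_value, criteria
            )
        delays, boots = {}, {}
        for rid in area_table.index[area_table["selected"]]:
            ca, cb = pairs[rid]
            fn = obs.leading_delay if edge == "leading" else obs.trailing_delay
            try:
                delays[rid] = fn(ca, cb, sw.maxima)
            except obs.ChordError:
                delays[rid] = None
                continue
            if not delays[rid].defined:
                continue
            try:
                boots[rid] = inf.bootstrap_observables(
                    tensor, (a, b),
                    inf.delay_observable((a, b), rid, edge, sw.maxima),
                    n_boot=cfg.inference.n_boot, seed=seed + 1,
                )
            except (inf.UnreliableBootstrapError, ValueError):
                # the edge is not stably estimable for this region; it
                # stays in the table without a z and cannot be selected
                continue
        delay_table = inf.select_delay_regions(area_table, delays, boots,
                                               criteria)
        delay_table.to_csv(out / f"delays_{tag}_{edge}.tsv", sep="\t")
        n_delay_selected[edge] = int(delay_table["selected"].sum())

    area_table.to_csv(out / f"area_{tag}.tsv", sep="\t")
    selected = area_table.index[area_table["selected"]]
    with open(out / f"curves_{tag}.tsv", "w") as fh:
        fh.write("region\tevent_class\tt\ty\n")
        for rid in selected:
            for cls, cur in ((a, curves_a[rid]), (b, curves_b[rid])):
                for t, y in cur.dense_sample(0.05):
                    fh.write(f"{rid}\t{cls}\t{t:.3f}\t{y:.6f}\n")
    man["analysis"][tag] = {
        "critical_value": perm.critical_value,
        "n_permutations": perm.n_permutations,
        "quantile": perm.quantile,
        "seed": seed,
        "n_area_selected": int(area_table["selected"].sum()),
        "n_delay_selected": n_delay_selected,
    }
    return area_table


def _decoding_stage(cfg, tensor, contrast, seed, out, man):
    a, b = contrast
    cv = dec.CVConfig(
        k=cfg.decoding.k, c_grid=tuple(cfg.decoding.c_grid),
        gamma_grid=tuple(cfg.decoding.gamma_grid), seed=seed,
        tune=cfg.decoding.tune,
    )
    tag = f"{a}-{b}"
    if cfg.decoding.per_tr:
        table = dec.per_tr_auc(tensor, (a, b), "logreg", cv)
        table.to_csv(out / f"per_tr_auc_{tag}.tsv", sep="\t")
        man["decoding"][f"{tag}_per_tr_argmax"] = int(table["mean_auc"].idxmax())
    feats = dec.build_features(tensor, (a, b))
    rows = []
    for model in cfg.decoding.models:
        res = dec.crossval_auc(feats, model, cv)
        rows.append({"model": res.model, "mean_auc": res.mean_auc,
                     "sd_auc": res.sd_auc})
    pd.DataFrame(rows).to_csv(out / f"window_auc_{tag}.tsv", sep="\t", index=False)
    man["decoding"][tag] = {"seed": seed, "models": rows}
    return feats


def _shapley_stage(cfg, feats, area_tables, criticals, contrast, seed, out, man):
    a, b = contrast
    tag = f"{a}-{b}"
    model = shapley.fit_gbdt(
        feats, seed=seed, n_estimators=cfg.shapley.n_estimators, n_jobs=1
    )
    sh = shapley.shapley_values(model, feats, "tree-exact")
    ranking = shapley.rank_features(sh)
    pruned = shapley.prune_and_retrain(
        {"name": "gbdt", "n_estimators": cfg.shapley.n_estimators, "n_jobs": 1},
        feats, ranking, cfg.shapley.keep_fraction,
        dec.CVConfig(k=cfg.decoding.k, seed=seed, tune="none"),
    )
    by_tr = shapley.aggregate_shapley(sh, by="tr", normalize=True)
    by_tr.to_csv(out / f"shapley_by_tr_{tag}.tsv", sep="\t", index=False)
    for stage_name, window in (("early", (0, 4)), ("late", (5, 9))):
        sums = shapley.aggregate_shapley(
            sh, by="region", window=window, normalize=True
        )
        table = area_tables.get((tag, stage_name))
        if table is not None:
            paired = shapley.shapley_vs_area(
                sums, table, criticals[(tag, stage_name)]
            )
            paired.to_csv(out / f"shapley_vs_area_{tag}_{stage_name}.tsv", sep="\t")
    man["shapley"][tag] = {
        "seed": seed,
        "efficiency_gap": sh.efficiency_gap,
        "keep_fraction": cfg.shapley.keep_fraction,
        "n_kept": int(len(pruned.kept_columns)),
        "auc_full": pruned.pre.mean_auc,
        "auc_pruned": pruned.post.mean_auc,
    }


ALL_STAGES = ("analysis", "decoding", "shapley")


def run_pipeline(cfg: RunConfig, out_dir, stages=ALL_STAGES) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the manifest (also written to ``manifest.json``): stage seeds,
    critical values, selected-region counts, drop counts, shapes and wall
    times -- every number in the reports traces back to an entry here.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = np.random.SeedSequence(cfg.seed).generate_state(16) % (2**31)
    stage_seed = {name: int(state[i]) for i, name in enumerate(
        ("data", "analysis", "decoding", "shapley")
    )}
    man: dict = {
        "config": asdict(cfg),
        "seeds": stage_seed,
        "stages": list(stages),
        "analysis": {},
        "decoding": {},
        "shapley": {},
        "timing_s": {},
    }

    t0 = time.perf_counter()
    tensor, dropped = prepare_trials(cfg, stage_seed["data"])
    man["n_trials"] = int(tensor.n_trials)
    man["n_dropped_trials"] = int(dropped)
    man["n_regions"] = len(tensor.region_ids)
    man["class_counts"] = tensor.class_counts()
    man["timing_s"]["data"] = round(time.perf_counter() - t0, 3)
    log.info("data: %d trials, %d regions, %d dropped (%.1fs)",
             tensor.n_trials, man["n_regions"], dropped, man["timing_s"]["data"])

    area_tables, criticals = {}, {}
    for ci, contrast in enumerate(cfg.contrasts):
        contrast = tuple(contrast)
        tag = f"{contrast[0]}-{contrast[1]}"
        if "analysis" in stages:
            t0 = time.perf_counter()
            for si, stage_name in enumerate(("early", "late")):
                table = _analysis_stage(
                    cfg, tensor, contrast, stage_name,
                    stage_seed["analysis"] + 10 * ci + si, out, man,
                )
                area_tables[(tag, stage_name)] = table
                criticals[(tag, stage_name)] = man["analysis"][
                    f"{tag}_{stage_name}"]["critical_value"]
            man["timing_s"][f"analysis_{tag}"] = round(time.perf_counter() - t0, 3)
        feats = None
        if "decoding" in stages:
            t0 = time.perf_counter()
            feats = _decoding_stage(
                cfg, tensor, contrast, stage_seed["decoding"] + ci, out, man
            )
            man["timing_s"][f"decoding_{tag}"] = round(time.perf_counter() - t0, 3)
        if "shapley" in stages and cfg.shapley.enabled:
            t0 = time.perf_counter()
            if feats is None:
                feats = dec.build_features(tensor, contrast)
            _shapley_stage(
                cfg, feats, area_tables, criticals, contrast,
                stage_seed["shapley"] + ci, out, man,
            )
            man["timing_s"][f"shapley_{tag}"] = round(time.perf_counter() - t0, 3)

    with open(out / "manifest.json", "w") as fh:
        json.dump(man, fh, indent=2, default=str)
    return man
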