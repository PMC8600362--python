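"""End-to-end orchestration: simulate -> spectra -> features -> scores ->
group statistics -> PCA / parallel analysis / regression -> report.

Two EEG paths are supported:

* ``timeseries`` — full signal synthesis, optional EDF round-trip, epoching,
  artifact screening and FFT spectra (the faithful pipeline);
* ``spectrum`` — direct simulation of the epoch-averaged spectrum
  (chi-square averaging noise on the analytic target density), used for
  large simulation studies.

Every stage writes tidy CSV outputs into the run directory and is driven by
one :class:`RunConfig` (YAML-serializable). A JSON manifest records the
seed, configuration, per-stage timing, output hashes and every subject
excluded for lacking a clear alpha peak, so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands, io, memory, pca_regression, simulate, spectral, stats

__all__ = ["RunConfig", "RunManifest", "CohortAnalysis", "analyze_cohort", "run_all", "load_config"]

_VERSION = "0.1.0"

#: the 15 per-condition parameter stems (each exists as _closed and _open)
PARAM_STEMS = tuple(dict.fromkeys(n.rsplit("_", 1)[0] for n in bands.FEATURE_NAMES))


@dataclass
class RunConfig:
    """All tunables of a synthetic run, validated up front."""

    cohort: simulate.CohortSpec = field(default_factory=simulate.CohortSpec)
    effects: simulate.EffectConfig = field(default_factory=simulate.EffectConfig)
    behavior: simulate.BehaviorConfig = field(default_factory=simulate.BehaviorConfig)
    eeg_mode: str = "timeseries"  # or "spectrum"
    write_edf: bool = False
    epoch_len: float = 1.0
    pad_factor: int = 2
    taper_fraction: float = spectral.DEFAULT_TAPER_FRACTION
    reject_threshold: float = spectral.DEFAULT_P2P_THRESHOLD
    highpass_hz: float | None = None  # synthetic data needs no filtering
    notch_hz: float | None = None
    search_range: tuple = bands.DEFAULT_SEARCH_RANGE
    prominence_threshold: float = bands.DEFAULT_PROMINENCE_THRESHOLD
    pa_iterations: int = 900
    pa_centile: float = 95.0
    alpha_level: float = 0.05

    def __post_init__(self):
        if self.eeg_mode not in ("timeseries", "spectrum"):
            raise ValueError(f"eeg_mode must be 'timeseries' or 'spectrum', got {self.eeg_mode!r}")
        if self.pa_iterations < 1:
            raise ValueError("pa_iterations must be >= 1")
        if not 0 < self.pa_centile <= 100:
            raise ValueError("pa_centile must be in (0, 100]")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        return d


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = simulate.CohortSpec(**kwargs["cohort"])
    if "effects" in kwargs:
        kwargs["effects"] = simulate.EffectConfig(**_rekey(kwargs["effects"]))
    if "behavior" in kwargs:
        kwargs["behavior"] = simulate.BehaviorConfig(**kwargs["behavior"])
    if "search_range" in kwargs:
        kwargs["search_range"] = tuple(kwargs["search_range"])
    return RunConfig(**kwargs)


def _rekey(d: dict) -> dict:
    """YAML round-trips tuple dict keys as strings; rebuild known tuple keys."""
    out = dict(d)
    if "bump_sd" in out and isinstance(out["bump_sd"], dict):
        out["bump_sd"] = {str(k): v for k, v in out["bump_sd"].items()}
    return out


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    stages: list
    exclusions: list
    outputs: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class CohortAnalysis:
    """In-memory result bundle of one full synthetic-cohort analysis."""

    profiles: list
    features: pd.DataFrame  # index subject_id, 'group' + 30 feature columns
    scores: pd.DataFrame  # subject_id, group, cbe, net
    excluded: list  # (subject_id, reason)
    trial_logs: dict = field(default_factory=dict)  # subject_id -> TrialLog
    pca: pca_regression.PCAResult | None = None
    pa: pca_regression.ParallelAnalysisResult | None = None
    models: dict = field(default_factory=dict)  # outcome -> {"full","simplified","nested"}
    slopes: dict = field(default_factory=dict)  # outcome -> {group: SlopeTest}


# ---------------------------------------------------------------------------
# core in-memory pipeline (the CLI stages wrap this with file I/O)
# ---------------------------------------------------------------------------


def _subject_rng(seed: int, index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, index, tag])


def subject_spectra(
    profile: simulate.SubjectProfile,
    index: int,
    config: RunConfig,
    eeg_dir: Path | None = None,
) -> dict[str, spectral.PowerSpectrum]:
    """Both conditions' scalp-averaged spectra for one subject."""
    spec = config.cohort
    out: dict[str, spectral.PowerSpectrum] = {}
    for ci, cond in enumerate(bands.CONDITIONS):
        rng = _subject_rng(spec.seed, index, 100 + ci)
        if config.eeg_mode == "spectrum":
            n_epochs = int(spec.n_segments_per_condition * spec.segment_len)
            out[cond] = simulate.simulate_spectrum(
                profile, cond, rng, config.effects, n_epochs=n_epochs, sfreq=spec.sfreq
            )
        else:
            sig = simulate.synthesize_eeg(profile, cond, spec, rng, config.effects)
            if eeg_dir is not None:
                path = eeg_dir / f"{profile.subject_id}_{cond}.edf"
                io.write_edf(path, sig, spec.sfreq)
                sig, sfreq, _ = io.read_eeg(path)
            else:
                sfreq = spec.sfreq
            out[cond] = spectral.subject_spectrum(
                sig,
                sfreq,
                condition=cond,
                epoch_len=config.epoch_len,
                taper_fraction=config.taper_fraction,
                pad_factor=config.pad_factor,
                peak_to_peak_threshold=config.reject_threshold,
                highpass_hz=config.highpass_hz,
                notch_hz=config.notch_hz,
            )
    return out


def analyze_cohort(config: RunConfig, eeg_dir: Path | None = None) -> CohortAnalysis:
    """Run the complete analysis on one simulated cohort, in memory."""
    spec = config.cohort
    profiles = simulate.sample_cohort(spec, config.effects)

    feature_rows, excluded = {}, []
    groups = {}
    for idx, prof in enumerate(profiles):
        spectra = subject_spectra(prof, idx, config, eeg_dir)
        groups[prof.subject_id] = prof.group
        try:
            feature_rows[prof.subject_id] = bands.extract_features(
                spectra, config.search_range, config.prominence_threshold
            )
        except bands.NoClearAlphaPeak as err:
            excluded.append((prof.subject_id, str(err)))

    features = pd.DataFrame.from_dict(feature_rows, orient="index")
    if not features.empty:
        features = features[list(bands.FEATURE_NAMES)]
        features.insert(0, "group", [groups[s] for s in features.index])
    features.index.name = "subject_id"

    score_rows, trial_logs = [], {}
    for idx, prof in enumerate(profiles):
        if prof.subject_id in excluded_ids(excluded):
            continue
        log = simulate.generate_trial_log(prof, config.behavior, _subject_rng(spec.seed, idx, 200))
        trial_logs[prof.subject_id] = log
        ms = memory.score_subject(log)
        score_rows.append(
            {"subject_id": prof.subject_id, "group": prof.group, "cbe": ms.cbe, "net": ms.net}
        )
    scores = pd.DataFrame(score_rows).set_index("subject_id") if score_rows else pd.DataFrame()

    analysis = CohortAnalysis(
        profiles=profiles, features=features, scores=scores, excluded=excluded,
        trial_logs=trial_logs,
    )
    _run_multivariate(analysis, config)
    return analysis


def excluded_ids(excluded: list) -> set:
    return {sid for sid, _ in excluded}


def _run_multivariate(analysis: CohortAnalysis, config: RunConfig) -> None:
    feats = analysis.features
    if len(feats) < 3 or feats.empty:
        raise ValueError(
            f"insufficient sample for PCA: {len(feats)} subject(s) with a clear "
            "alpha peak in both conditions"
        )
    X = feats[list(bands.FEATURE_NAMES)].to_numpy()
    Z = pca_regression.zscore_features(X, list(bands.FEATURE_NAMES))
    analysis.pca = pca_regression.run_pca(Z, bands.FEATURE_NAMES)
    analysis.pa = pca_regression.parallel_analysis(
        Z,
        n_iter=config.pa_iterations,
        centile=config.pa_centile,
        seed=np.random.default_rng([config.cohort.seed & 0x7FFFFFFF, 777]),
    )
    n_retained = analysis.pa.n_retained
    if n_retained < 1:
        raise ValueError("parallel analysis retained no components; cannot fit regressions")
    scores_mat = analysis.pca.scores[:, :n_retained]
    aligned = analysis.scores.loc[feats.index]
    for outcome in ("cbe", "net"):
        full = pca_regression.fit_interaction_model(
            scores_mat, feats["group"].tolist(), aligned[outcome].to_numpy(), outcome_name=outcome
        )
        simplified = pca_regression.simplify_aic(full)
        nested = pca_regression.nested_f_test(full, simplified)
        analysis.models[outcome] = {"full": full, "simplified": simplified, "nested": nested}
        if "comp_1" in simplified.terms and "age:comp_1" in simplified.terms:
            analysis.slopes[outcome] = pca_regression.group_slopes(simplified, 1)
        elif "comp_1" in full.terms:
            analysis.slopes[outcome] = pca_regression.group_slopes(full, 1)


# ---------------------------------------------------------------------------
# univariate statistics tables
# ---------------------------------------------------------------------------


def eeg_group_stats(features: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter 2x2 mixed ANOVA plus per-condition/per-group t tests."""
    rows = []
    for stem in PARAM_STEMS:
        closed = features[f"{stem}_closed"]
        open_ = features[f"{stem}_open"]
        group = features["group"]
        an = stats.mixed_anova_2x2(closed.to_dict(), open_.to_dict(), group.to_dict())
        for effect_name, eff in (
            ("age_group", an.group),
            ("eye_condition", an.condition),
            ("interaction", an.interaction),
        ):
            rows.append(
                dict(parameter=stem, effect=effect_name, stat="F", value=eff.F,
                     df1=eff.df_num, df2=eff.df_den, p=eff.p, effect_size=eff.eta2p,
                     effect_size_name="eta2p")
            )
        for cond, series in (("closed", closed), ("open", open_)):
            tt = stats.independent_t(
                series[group == "young"].to_numpy(), series[group == "older"].to_numpy()
            )
            rows.append(
                dict(parameter=stem, effect=f"young_vs_older_{cond}", stat="t", value=tt.t,
                     df1=tt.df, df2=np.nan, p=tt.p, effect_size=tt.effect,
                     effect_size_name="d_s")
            )
        for g in ("young", "older"):
            sel = group == g
            tt = stats.paired_t(closed[sel].to_numpy(), open_[sel].to_numpy())
            rows.append(
                dict(parameter=stem, effect=f"closed_vs_open_{g}", stat="t", value=tt.t,
                     df1=tt.df, df2=np.nan, p=tt.p, effect_size=tt.effect,
                     effect_size_name="d_z")
            )
    return pd.DataFrame(rows)


def behavior_group_stats(scores: pd.DataFrame) -> pd.DataFrame:
    """Independent t comparisons of CBE and NET between groups."""
    rows = []
    for measure in ("cbe", "net"):
        young = scores.loc[scores["group"] == "young", measure].to_numpy()
        older = scores.loc[scores["group"] == "older", measure].to_numpy()
        tt = stats.independent_t(young, older)
        rows.append(
            dict(measure=measure, young_mean=young.mean(), young_sd=young.std(ddof=1),
                 older_mean=older.mean(), older_sd=older.std(ddof=1),
                 t=tt.t, df=tt.df, p=tt.p, d_s=tt.effect)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------


def _model_frame(model: pca_regression.RegressionModel) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "term": list(model.terms),
            "beta": [model.params[t] for t in model.terms],
            "se": [model.bse[t] for t in model.terms],
            "t": [model.tvalues[t] for t in model.terms],
            "p": [model.pvalues[t] for t in model.terms],
        }
    )
    df["r2"] = model.r2
    df["adj_r2"] = model.adj_r2
    df["aic"] = model.aic
    df["df_resid"] = model.df_resid
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir) -> RunManifest:
    """Execute the full pipeline into ``out_dir`` and write the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    outputs: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = True):
        path = out_dir / name
        frame.to_csv(path, index=index)
        outputs[name] = _sha256(path)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            stages.append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})

        return wrap

    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    outputs["config.yaml"] = _sha256(out_dir / "config.yaml")

    eeg_dir = None
    if config.write_edf and config.eeg_mode == "timeseries":
        eeg_dir = out_dir / "eeg"
        eeg_dir.mkdir(exist_ok=True)

    holder: dict = {}

    @stage("analysis")
    def _():
        holder["analysis"] = analyze_cohort(config, eeg_dir)

    analysis: CohortAnalysis = holder["analysis"]

    @stage("tables")
    def _():
        save("profiles.csv", profiles_frame(analysis.profiles))
        save("trials.csv", trials_frame(analysis.trial_logs), index=False)
        save("features.csv", analysis.features)
        save("scores.csv", analysis.scores)
        save(
            "exclusions.csv",
            pd.DataFrame(analysis.excluded, columns=["subject_id", "reason"]),
            index=False,
        )

    @stage("group_stats")
    def _():
        save("eeg_group_stats.csv", eeg_group_stats(analysis.features), index=False)
        save("behavior_stats.csv", behavior_group_stats(analysis.scores), index=False)

    @stage("pca_regression")
    def _():
        pca, pa = analysis.pca, analysis.pa
        eig = pd.DataFrame(
            {
                "component": np.arange(1, len(pca.eigenvalues) + 1),
                "eigenvalue": pca.eigenvalues,
                "null_percentile": pa.null_percentiles,
                "adjusted": pa.adjusted,
                "retained": pa.adjusted > 1.0,
                "variance_explained": pca.variance_explained,
                "cumulative_variance": pca.cumulative_variance,
            }
        )
        save("pca_eigenvalues.csv", eig, index=False)
        load = pd.DataFrame(
            pca.loadings[:, : pa.n_retained],
            index=list(pca.feature_names),
            columns=[f"comp_{k}" for k in range(1, pa.n_retained + 1)],
        )
        load.index.name = "feature"
        save("pca_loadings.csv", load)
        sc = pd.DataFrame(
            pca.scores[:, : pa.n_retained],
            index=analysis.features.index,
            columns=[f"comp_{k}" for k in range(1, pa.n_retained + 1)],
        )
        save("pca_scores.csv", sc)
        for outcome, bundle in analysis.models.items():
            save(f"model_{outcome}_full.csv", _model_frame(bundle["full"]), index=False)
            save(f"model_{outcome}_simplified.csv", _model_frame(bundle["simplified"]), index=False)
        slope_rows = [
            dataclasses.asdict(st)
            for outcome, per_group in analysis.slopes.items()
            for st in per_group.values()
        ]
        if slope_rows:
            save("slopes.csv", pd.DataFrame(slope_rows), index=False)

    @stage("report")
    def _():
        text = render_report(analysis)
        (out_dir / "report.txt").write_text(text)
        outputs["report.txt"] = _sha256(out_dir / "report.txt")

    manifest = RunManifest(
        seed=config.cohort.seed,
        version=_VERSION,
        config=config.to_dict(),
        stages=stages,
        exclusions=[{"subject_id": s, "reason": r} for s, r in analysis.excluded],
        outputs=outputs,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def profiles_frame(profiles: list) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "group": p.group,
            "iapf_closed": p.iapf["closed"],
            "iapf_open": p.iapf["open"],
            "aperiodic_offset": p.aperiodic_offset,
            "aperiodic_exponent": p.aperiodic_exponent,
            "noise_sd": p.noise_sd,
            "latent_factor": p.latent_factor,
        }
        for (band, cond), amp in p.band_amplitudes.items():
            row[f"amp_{band}_{cond}"] = amp
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def trials_frame(trial_logs: dict) -> pd.DataFrame:
    """Tidy trial-log table: one row per trial, pads joined with '|'."""
    rows = []
    for sid, log in trial_logs.items():
        for i, trial in enumerate(log.trials):
            rows.append(
                {
                    "subject_id": sid,
                    "trial": i + 1,
                    "goals": "|".join(str(g) for g in sorted(trial.goals)),
                    "visits": "|".join(str(v) for v in trial.visits),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "trial", "goals", "visits"])


def frame_to_trial_logs(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`trials_frame`."""
    logs: dict = {}
    for sid, sub in frame.groupby("subject_id", sort=False):
        trials = tuple(
            memory.Trial(
                goals=frozenset(int(g) for g in str(row["goals"]).split("|")),
                visits=tuple(int(v) for v in str(row["visits"]).split("|")),
            )
            for _, row in sub.sort_values("trial").iterrows()
        )
        logs[sid] = memory.TrialLog(trials=trials)
    return logs


def spectra_frame(all_spectra: dict) -> pd.DataFrame:
    """Tidy spectra table (subject_id, condition, freq, power, n_epochs_used)."""
    rows = []
    for sid, per_cond in all_spectra.items():
        for cond, ps in per_cond.items():
            for f, p in zip(ps.freqs, ps.power):
                rows.append(
                    {"subject_id": sid, "condition": cond, "freq": f, "power": p,
                     "n_epochs_used": ps.n_epochs_used}
                )
    return pd.DataFrame(rows)


def frame_to_spectra(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`spectra_frame`."""
    out: dict = {}
    for (sid, cond), sub in frame.groupby(["subject_id", "condition"], sort=False):
        sub = sub.sort_values("freq")
        out.setdefault(sid, {})[cond] = spectral.PowerSpectrum(
            freqs=sub["freq"].to_numpy(),
            power=sub["power"].to_numpy(),
            n_epochs_used=int(sub["n_epochs_used"].iloc[0]),
            condition=cond,
        )
    return out


def render_report(analysis: CohortAnalysis) -> str:
    """Plain-text summary mirroring the result tables."""
    lines = []
    n_young = int((analysis.features["group"] == "young").sum())
    n_older = int((analysis.features["group"] == "older").sum())
    lines.append("Resting-state EEG band parameters and spatial working memory")
    lines.append("=" * 62)
    lines.append(
        f"Final sample: {n_young} young, {n_older} older "
        f"({len(analysis.excluded)} excluded: no clear alpha peak)"
    )
    beh = behavior_group_stats(analysis.scores)
    for _, r in beh.iterrows():
        lines.append(
            f"{r['measure'].upper()}: young M={r['young_mean']:.2f} SD={r['young_sd']:.2f}, "
            f"older M={r['older_mean']:.2f} SD={r['older_sd']:.2f}; "
            f"t({r['df']:.0f})={r['t']:.3f}, p={r['p']:.3g}, d_s={r['d_s']:.3f}"
        )
    if analysis.pa is not None:
        pa = analysis.pa
        lines.append(
            f"Parallel analysis: {pa.n_retained} component(s) retained "
            f"(adjusted eigenvalues > 1); cumulative variance "
            f"{analysis.pca.cumulative_variance[max(pa.n_retained - 1, 0)] * 100:.2f}%"
        )
    for outcome, bundle in analysis.models.items():
        s = bundle["simplified"]
        d_r2, F, dfn, dfd, p = bundle["nested"]
        lines.append(
            f"{outcome.upper()} simplified model: R2={s.r2:.2f}, adj R2={s.adj_r2:.2f}, "
            f"AIC={s.aic:.1f}; vs full: dR2={d_r2:.3f}, F({dfn},{dfd})={F:.3f}, p={p:.3f}"
        )
        if outcome in analysis.slopes:
            for g, st in analysis.slopes[outcome].items():
                lines.append(
                    f"  {outcome.upper()} ~ comp 1 slope in {g}: {st.slope:.3f} "
                    f"(SE {st.se:.3f}), t({st.df})={st.t:.3f}, p={st.p:.3f}"
                )
    return "\n".join(lines) + "\n"
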