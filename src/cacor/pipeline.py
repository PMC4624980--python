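"""Top-level analyses gluing the stages together.

Two analyses mirror the study design: the *presentation analysis*
(per-presentation CACor with significance, per-stimulus CACor scores and
Grand-Average CACor) and the *profile / within-stimulus analyses*
(Spearman correlations between per-stimulus score profiles and feature
profiles; partial correlations between the time-resolved group CACor or
mean tension ratings and the nine music features).

A study is either loaded from a JSON manifest on disk (``StudyLayout``)
or built synthetically in memory (``build_synthetic_study``).  Every
source of randomness derives from the run seed, so reruns are
bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_features as af
from . import cacor_stats as cs
from . import eeg_regression as er
from .config import RunConfig
from .data_io import read_eeg, read_ratings, read_wav

logger = logging.getLogger("cacor")

__all__ = [
    "StudyData",
    "StudyLayout",
    "build_synthetic_study",
    "run_presentation_analysis",
    "run_profile_analysis",
    "run_within_stimulus_analysis",
]


@dataclass
class StudyData:
    """In-memory study: slopes, EEG recordings and optional extras.

    ``recordings[stimulus][subject]`` is the list of >= 3 presentations;
    ``slopes[stimulus]`` the power slope on the EEG grid.
    """

    slopes: dict
    recordings: dict
    waveforms: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)   # stimulus -> {name: FeatureSeries}
    ratings: dict = field(default_factory=dict)    # stimulus -> RatingSet
    ground_truth: dict = field(default_factory=dict)

    def stimuli(self):
        return list(self.recordings)


@dataclass
class StudyLayout:
    """Manifest mapping (subject, stimulus, presentation) to files.

    JSON structure::

        {"stimuli": {"stim1": {"audio": "stim1.wav", "ratings": "r1.csv"}},
         "eeg": [{"subject": "S1", "stimulus": "stim1", "presentation": 1,
                  "path": "S1_stim1_1.csv", "sidecar": "S1_stim1_1.meta"}]}
    """

    stimuli: dict
    eeg: list
    root: Path = Path(".")

    @classmethod
    def from_file(cls, path) -> "StudyLayout":
        path = Path(path)
        d = json.loads(path.read_text())
        layout = cls(stimuli=d["stimuli"], eeg=d["eeg"], root=path.parent)
        layout.validate()
        return layout

    def validate(self):
        counts = {}
        for entry in self.eeg:
            if not (self.root / entry["path"]).exists():
                raise FileNotFoundError(self.root / entry["path"])
            key = (entry["subject"], entry["stimulus"])
            counts[key] = counts.get(key, 0) + 1
        for stim, files in self.stimuli.items():
            for f in files.values():
                if not (self.root / f).exists():
                    raise FileNotFoundError(self.root / f)
        self.presentation_counts = counts

    def load(self, cfg: RunConfig | None = None) -> StudyData:
        cfg = cfg or RunConfig()
        slopes, waveforms, features, ratings = {}, {}, {}, {}
        for stim, files in self.stimuli.items():
            if "audio" in files:
                w = read_wav(self.root / files["audio"])
                waveforms[stim] = w
                p = af.frame_power(w, cfg.frame_len, cfg.frame_overlap)
                slopes[stim] = af.power_slope(p, cfg.eeg_rate, duration=w.duration).values
                features[stim] = af.extract_all_features(w)
            if "ratings" in files:
                ratings[stim] = read_ratings(
                    self.root / files["ratings"], rate=cfg.rating_rate, stimulus_id=stim
                )
        recordings = {}
        for entry in self.eeg:
            rec = read_eeg(
                self.root / entry["path"],
                metadata=self.root / entry["sidecar"] if "sidecar" in entry else None,
                subject_id=entry["subject"],
                stimulus_id=entry["stimulus"],
                presentation_index=int(entry["presentation"]),
            )
            if rec.rate != cfg.eeg_rate:
                rec = er.preprocess(
                    rec, cfg.eeg_rate, cfg.lowpass_pass, cfg.lowpass_stop, cfg.highpass
                )
            recordings.setdefault(entry["stimulus"], {}).setdefault(
                entry["subject"], []
            ).append(rec)
        for stim, by_subj in recordings.items():
            for subj, recs in by_subj.items():
                recs.sort(key=lambda r: r.presentation_index)
                if len(recs) < 3:
                    raise ValueError(
                        f"{subj}/{stim}: {len(recs)} presentations; "
                        "leave-one-recording-out needs at least 3"
                    )
        return StudyData(
            slopes=slopes,
            recordings=recordings,
            waveforms=waveforms,
            features=features,
            ratings=ratings,
        )


def build_synthetic_study(
    scenarios,
    channel_labels=None,
    seed: int = 0,
    kernel=None,
    with_ratings: bool = False,
    rating_coupling_from: str = "coupling",
) -> StudyData:
    """Simulate a full study from a list of ``SimScenario``.

    Per scenario one tone-sequence stimulus is synthesised and
    ``n_subjects x n_presentations`` EEG recordings are generated from
    independent child seeds; the per-scenario coupling/snr set the
    planted response strength.  Ground truth (couplings, onsets, kernel)
    is kept for validation.
    """
    from . import synthetic_data as sd

    channel_labels = list(channel_labels) if channel_labels else list(sd.STANDARD_61)
    kernel = kernel or sd.KernelSpec()
    root_ss = np.random.SeedSequence(seed)
    slopes, waveforms, recordings, features, ratings = {}, {}, {}, {}, {}
    truth = {"coupling": {}, "snr": {}, "onsets": {}, "kernel": kernel}
    for i, scen in enumerate(scenarios):
        ss_audio, ss_eeg, ss_rate = np.random.SeedSequence(
            entropy=(seed, i)
        ).spawn(3)
        w, onsets = sd.synth_tone_sequence(
            ioi=scen.ioi,
            chord_len=scen.chord_len,
            rise_fall=scen.rise_fall,
            duration=scen.duration,
            rate=scen.audio_rate,
            jitter=scen.jitter,
            seed=np.random.default_rng(ss_audio),
        )
        stim = scen.stimulus_id
        waveforms[stim] = w
        slope = sd.slope_of(w)
        slopes[stim] = slope
        features[stim] = af.extract_all_features(w)
        truth["coupling"][stim] = scen.coupling
        truth["snr"][stim] = scen.snr
        truth["onsets"][stim] = onsets
        rng = np.random.default_rng(ss_eeg)
        by_subj = {}
        for s in range(scen.n_subjects):
            subj = f"S{s + 1}"
            by_subj[subj] = [
                sd.synth_eeg(
                    slope,
                    spec=kernel,
                    snr=scen.snr,
                    coupling=scen.coupling,
                    channel_labels=channel_labels,
                    alpha_amp=scen.alpha_amp,
                    seed=rng,
                    subject_id=subj,
                    stimulus_id=stim,
                    presentation_index=p + 1,
                )
                for p in range(scen.n_presentations)
            ]
        recordings[stim] = by_subj
        if with_ratings:
            # intensity macro-structure drives the shared tension course
            p = af.frame_power(w)
            latent = np.interp(
                np.arange(int(scen.duration * 50)) / 50.0, p.times, p.values
            )
            ratings[stim] = sd.synth_ratings(
                latent,
                coupling=scen.coupling * 0.9,
                seed=np.random.default_rng(ss_rate),
                stimulus_id=stim,
            )
    return StudyData(
        slopes=slopes,
        recordings=recordings,
        waveforms=waveforms,
        features=features,
        ratings=ratings,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# analyses


def run_presentation_analysis(study: StudyData, cfg: RunConfig | None = None):
    """Per-presentation CACor table, per-stimulus scores, Grand Averages.

    For every (stimulus, subject) the three presentations are projected
    with leave-one-recording-out filters; each projection's CACor gets a
    surrogate and a Pyper p-value, Bonferroni-corrected over the
    stimulus' presentation count.  Returns ``(table, scores, ga)`` where
    ``scores`` maps stimulus -> CACor score for both significance routes.
    """
    cfg = cfg or RunConfig()
    rows = []
    scores: dict = {"perm": {}, "pyper": {}}
    ga: dict = {}
    for si, stim in enumerate(sorted(study.recordings)):
        slope = study.slopes[stim]
        by_subj = study.recordings[stim]
        stim_rows = []
        projections = []
        for subj_idx, subj in enumerate(sorted(by_subj)):
            recs = by_subj[subj]
            if len(recs) < 3:
                logger.warning("%s/%s: skipped (fewer than 3 presentations)", subj, stim)
                continue
            projs, _ = er.crossval_projections(recs, slope, n_lags=cfg.n_lags)
            for proj in projs:
                seed = np.random.SeedSequence(
                    entropy=(cfg.seed, si, subj_idx, proj.presentation_index)
                )
                r = cs.cacor(proj, slope)
                alt = "greater" if cfg.one_sided else "two-sided"
                p_perm = cs.surrogate_test(
                    proj,
                    slope,
                    n_surr=cfg.n_surrogates,
                    seed=np.random.default_rng(seed),
                    alternative=alt,
                )
                x, yy = cs._as_pair(proj, slope)
                n_eff, p_pyper = cs.pyper_effective_df(
                    x, yy, rate=proj.rate, max_lag=cfg.pyper_max_lag, r=r, alternative=alt
                )
                stim_rows.append(
                    dict(
                        stimulus=stim,
                        subject=subj,
                        presentation=proj.presentation_index,
                        r=r,
                        p_perm=p_perm,
                        p_pyper=p_pyper,
                        n_eff=n_eff,
                    )
                )
                projections.append(proj)
        if not stim_rows:
            logger.warning("stimulus %s skipped entirely", stim)
            continue
        n_pres = len(stim_rows)
        for key in ("perm", "pyper"):
            flags = cs.correct_presentations(
                [row[f"p_{key}"] for row in stim_rows], n_pres, cfg.alpha
            )
            for row, flag in zip(stim_rows, flags):
                row[f"sig_{key}"] = bool(flag)
            scores[key][stim] = cs.cacor_score(flags)
        ga[stim] = cs.grand_average_cacor(
            projections,
            slope,
            n_surr=cfg.n_surrogates,
            seed=np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, si, 2**33))),
            max_lag=cfg.pyper_max_lag,
            alpha=cfg.alpha,
            alternative="greater" if cfg.one_sided else "two-sided",
        )
        rows.extend(stim_rows)
    table = pd.DataFrame(rows)
    return table, scores, ga


def run_profile_analysis(
    scores: dict, feature_profile: pd.DataFrame, coordination: dict | None = None
) -> pd.DataFrame:
    """Spearman correlations between the CACor score profile and each
    feature profile (plus the Coordination profile when given)."""
    rows = []
    for feat in feature_profile.columns:
        prof = feature_profile[feat].to_dict()
        rho, p = cs.profile_correlation(scores, prof)
        rows.append(dict(profile=feat, rho=rho, p=p))
    if coordination is not None:
        rho, p = cs.profile_correlation(scores, coordination)
        rows.append(dict(profile="coordination_score", rho=rho, p=p))
    out = pd.DataFrame(rows).set_index("profile")
    out["significant"] = out["p"] <= 0.05
    return out


def _features_on_grid(features: dict, trc_rate: float, n: int) -> pd.DataFrame:
    cols = {}
    for name, series in features.items():
        res = af.resample_series(series, trc_rate)
        v = res.values
        v = v[:n] if len(v) >= n else np.pad(v, (0, n - len(v)), constant_values=np.nan)
        cols[name] = v
    return pd.DataFrame(cols)


def run_within_stimulus_analysis(
    ga_projection,
    slope,
    features: dict,
    mean_ratings=None,
    cfg: RunConfig | None = None,
):
    """Partial correlations of the time-resolved CACor (and mean tension
    ratings) with each music feature, controls = the remaining features.

    Returns a 9-features x targets DataFrame of partial r and
    FDR-flagged Pyper-corrected p-values.
    """
    cfg = cfg or RunConfig()
    trc = cs.time_resolved_cacor(
        ga_projection, slope, window_len=cfg.tr_window, overlap=cfg.tr_overlap
    )
    n = len(trc)
    F = _features_on_grid(features, trc.rate, n)
    targets = {"cacor": trc.values}
    if mean_ratings is not None:
        v = np.asarray(mean_ratings, dtype=float)
        v = v[:n] if len(v) >= n else np.pad(v, (0, n - len(v)), constant_values=np.nan)
        targets["tension"] = v
    rows = []
    for tname, tvals in targets.items():
        for feat in F.columns:
            controls = [F[c].to_numpy() for c in F.columns if c != feat]
            try:
                r, p = cs.partial_correlation(
                    tvals,
                    F[feat].to_numpy(),
                    controls,
                    rate=trc.rate,
                    max_lag=cfg.pyper_max_lag_partial,
                )
            except ValueError:
                r, p = np.nan, np.nan
            rows.append(dict(target=tname, feature=feat, partial_r=r, p=p))
    out = pd.DataFrame(rows)
    for tname in targets:
        m = out["target"] == tname
        out.loc[m, "significant"] = cs.fdr_correct(out.loc[m, "p"], q=cfg.fdr_q)
    return out
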