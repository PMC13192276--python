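"""Experiment grids, behavioural scoring, psychometric thresholds,
human-model similarity metrics, the permutation interaction test and
the stage-of-selection analysis.

Grid builders are pure functions of (experiment id, grid parameters):
they enumerate every stimulus cell of the model-side experiments
(distractor type x SNR x spatial configuration ...) as specification
dicts, without rendering audio.  At paper-scale parameters the cell
counts reproduce the printed totals; at desk scale the same factorial
structure is built over a smaller catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TrialRecord", "PsychometricCurve", "ThresholdTable", "SimilarityReport",
    "GridParams", "build_experiment_grid", "score_trial",
    "estimate_threshold", "spatial_release", "similarity", "sign_test",
    "permutation_interaction", "mutual_information", "stage_selection",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = ("1", "1b", "2", "3", "4", "5", "6", "7")

EXP1_DISTRACTOR_TYPES = (
    "one_talker_same_sex", "one_talker_diff_sex", "two_talker",
    "four_talker", "babble_8talker", "mandarin_one_talker",
    "stationary_noise", "auditory_scene", "music",
)
EXP1_SNRS = (-9.0, -6.0, -3.0, 0.0, 3.0)
EXP1B_CUE_DURATIONS = (0.5, 1.0, 2.0)
EXP2_MODES = ("harmonic", "inharmonic", "whispered")
EXP4_OFFSETS = (0.0, 5.0, 10.0, 20.0, 40.0)
EXP4_SNRS = tuple(float(s) for s in range(-18, 7, 3))
EXP5_CONDITIONS = ("colocated", "separated", "illusory_separated")
EXP5_SNRS = (-12.0, -8.0, -4.0, 0.0)
EXP6_OFFSETS = (("none", 0.0), ("azimuth", 10.0), ("azimuth", 60.0),
                ("elevation", 10.0), ("elevation", 60.0))
EXP6_SNRS = (-9.0, -6.0, -3.0, 0.0, 3.0, 6.0)
EXP7_TARGET_AZIMUTHS = (0.0, 90.0)
EXP7_OFFSETS = (0.0, 10.0, 30.0, 90.0)


@dataclass
class TrialRecord:
    """One behavioural/model trial."""

    condition: dict
    response: int | str
    target_words: list
    distractor_words: list = field(default_factory=list)


@dataclass
class PsychometricCurve:
    snr_db: np.ndarray
    proportion_correct: np.ndarray

    def __post_init__(self):
        self.snr_db = np.asarray(self.snr_db, dtype=float)
        self.proportion_correct = np.asarray(self.proportion_correct,
                                             dtype=float)
        if len(self.snr_db) != len(self.proportion_correct):
            raise ValueError("axis length mismatch")
        if np.any((self.proportion_correct < 0)
                  | (self.proportion_correct > 1)):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass
class ThresholdTable:
    """thresholds[participant, direction, offset] in dB SNR."""

    thresholds: np.ndarray
    directions: tuple = ("azimuth", "elevation")
    offsets: tuple = (0.0, 10.0, 60.0)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 3:
            raise ValueError("expect (participants, directions, offsets)")
        if not np.all(np.isfinite(t)):
            raise ValueError("incomplete factorial cells")
        self.thresholds = t


@dataclass
class SimilarityReport:
    rmse: float
    pearson_r2: float
    mutual_information: dict            # bin count -> bits
    rmse_ci: tuple = None
    r2_ci: tuple = None
    mi_ci: dict = None
    r_undefined: bool = False


# ---------------------------------------------------------------------
# experiment grids
# ---------------------------------------------------------------------

@dataclass
class GridParams:
    """Catalog sizes driving grid enumeration.  Defaults are paper scale;
    pass smaller numbers for desk-scale grids of identical structure."""

    n_targets: int = 976              # target clips (2 talker sexes x words)
    n_exp3_excerpts: int = 376
    n_exp3_textures: int = 43


def build_experiment_grid(experiment_id: str,
                          params: GridParams | None = None) -> list:
    """Deterministic enumeration of every stimulus cell of an experiment.

    Returns a list of dicts with condition fields; `len()` of the result
    is the experiment's stimulus count.
    """
    p = params or GridParams()
    eid = str(experiment_id)
    if eid not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    n_pairs = 2 * p.n_targets         # same- and different-sex pairings
    grid = []
    if eid == "1":
        for t in range(p.n_targets):
            grid.append({"experiment": "1", "target": t,
                         "distractor_type": "none", "snr_db": np.inf})
        for t in range(p.n_targets):
            for dt in EXP1_DISTRACTOR_TYPES:
                for snr in EXP1_SNRS:
                    grid.append({"experiment": "1", "target": t,
                                 "distractor_type": dt, "snr_db": snr})
    elif eid == "1b":
        for t in range(p.n_targets):
            for dur in EXP1B_CUE_DURATIONS:
                for sex in ("same", "different"):
                    grid.append({"experiment": "1b", "target": t,
                                 "cue_duration_s": dur,
                                 "distractor_sex": sex, "snr_db": 0.0})
    elif eid == "2":
        for t in range(p.n_targets):
            for sex in ("same", "different"):
                for tm in EXP2_MODES:
                    grid.append({"experiment": "2", "target": t,
                                 "distractor_sex": sex,
                                 "target_mode": tm, "distractor_mode": "none",
                                 "snr_db": np.inf})
                    for dm in EXP2_MODES:
                        grid.append({"experiment": "2", "target": t,
                                     "distractor_sex": sex,
                                     "target_mode": tm, "distractor_mode": dm,
                                     "snr_db": 0.0})
    elif eid == "3":
        for t in range(p.n_exp3_excerpts):
            for tx in range(p.n_exp3_textures):
                grid.append({"experiment": "3", "target": t, "texture": tx,
                             "snr_db": -3.0})
    elif eid == "4":
        for t in range(p.n_targets):
            for off in EXP4_OFFSETS:
                for snr in EXP4_SNRS:
                    grid.append({"experiment": "4", "target": t,
                                 "offset_deg": off, "snr_db": snr,
                                 "n_distractors": 2, "symmetric": True})
    elif eid == "5":
        for t in range(n_pairs):
            for cond in EXP5_CONDITIONS:
                for snr in EXP5_SNRS:
                    grid.append({"experiment": "5", "pair": t,
                                 "condition": cond, "snr_db": snr,
                                 "lead_lag_delay_s": 0.004})
    elif eid == "6":
        for t in range(n_pairs):
            for direction, off in EXP6_OFFSETS:
                for snr in EXP6_SNRS:
                    grid.append({"experiment": "6", "pair": t,
                                 "offset_direction": direction,
                                 "offset_deg": off, "snr_db": snr,
                                 "n_distractors": 2})
    elif eid == "7":
        for t in range(n_pairs):
            for taz in EXP7_TARGET_AZIMUTHS:
                for off in EXP7_OFFSETS:
                    grid.append({"experiment": "7", "pair": t,
                                 "target_azimuth": taz, "offset_deg": off,
                                 "snr_db": 0.0, "n_distractors": 1})
    return grid


# ---------------------------------------------------------------------
# scoring and thresholds
# ---------------------------------------------------------------------

def trial_records_to_csv(records, path) -> None:
    """One row per trial: condition columns plus response/transcripts
    (word lists serialized as ';'-joined strings)."""
    import pandas as pd
    rows = []
    for r in records:
        row = dict(r.condition)
        row["response"] = r.response
        row["target_words"] = ";".join(str(w) for w in r.target_words)
        row["distractor_words"] = ";".join(str(w)
                                           for w in r.distractor_words)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trial_records_from_csv(path, word_type=int) -> list:
    """Read trial rows back (also suits externally published trial CSVs
    using the same response/target/distractor column schema)."""
    import pandas as pd
    df = pd.read_csv(path, dtype={"target_words": str,
                                  "distractor_words": str},
                     keep_default_na=False)

    def split(v):
        if v == "" or v is None:
            return []
        return [word_type(w) for w in str(v).split(";")]

    records = []
    cond_cols = [c for c in df.columns
                 if c not in ("response", "target_words", "distractor_words")]
    for _, row in df.iterrows():
        records.append(TrialRecord(
            condition={c: row[c] for c in cond_cols},
            response=word_type(row["response"]),
            target_words=split(row["target_words"]),
            distractor_words=split(row["distractor_words"])))
    return records


def score_trial(record: TrialRecord) -> dict:
    """Correct iff the response is any in-vocabulary word of the target
    transcript; confusion iff it is a distractor-transcript word and not
    correct (correct takes precedence)."""
    resp = record.response
    if resp is None or resp == "":
        return {"correct": False, "confusion": False}
    correct = resp in record.target_words
    confusion = (not correct) and (resp in record.distractor_words)
    return {"correct": bool(correct), "confusion": bool(confusion)}


def estimate_threshold(curve: PsychometricCurve,
                       criterion: str = "half_max") -> float:
    """SNR at criterion performance from a least-squares quadratic fit.

    half_max: 0.5 x maximum of the fitted curve within the tested range;
    fixed_50: absolute 0.5.  Picks the criterion crossing with positive
    fitted slope inside the tested SNR span; NaN if never attained.
    """
    x, y = curve.snr_db, curve.proportion_correct
    if len(x) < 3:
        raise ValueError("need at least 3 SNR points")
    coef = np.polyfit(x, y, 2)
    poly = np.poly1d(coef)
    lo, hi = float(x.min()), float(x.max())
    if criterion == "half_max":
        xs = np.linspace(lo, hi, 512)
        level = 0.5 * float(poly(xs).max())
    elif criterion == "fixed_50":
        level = 0.5
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    roots = np.roots(coef - np.array([0.0, 0.0, level]))
    dpoly = poly.deriv()
    cands = [float(r.real) for r in roots
             if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9
             and dpoly(r.real) > 0]
    if not cands:
        return float("nan")
    return min(cands)


def spatial_release(thresholds: dict, colocated_key=0.0) -> dict:
    """SRM(offset) = threshold(colocated) - threshold(offset), in dB."""
    if colocated_key not in thresholds:
        raise ValueError("colocated cell missing")
    base = thresholds[colocated_key]
    return {k: base - v for k, v in thresholds.items()}


# ---------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------

def mutual_information(x, y, bins: int) -> float:
    """Plug-in MI (bits) from a joint 2-D histogram; bin edges span the
    pooled min-max of both vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


def similarity(human_means, model_means, n_boot: int = 1000,
               mi_bins=(5, 10, 15, 20),
               rng: np.random.Generator | None = None) -> SimilarityReport:
    """RMSE, Pearson r^2 and MI between condition-mean vectors, with
    bootstrap CIs obtained by resampling experimental conditions."""
    h = np.asarray(human_means, float)
    m = np.asarray(model_means, float)
    if h.shape != m.shape or h.ndim != 1 or len(h) < 3:
        raise ValueError("need equal-length vectors over >= 3 conditions")
    rng = rng or np.random.default_rng(0)
    rmse = float(np.sqrt(np.mean((h - m) ** 2)))
    r_undef = h.std() == 0 or m.std() == 0
    r2 = float("nan") if r_undef else float(stats.pearsonr(h, m)[0] ** 2)
    mi = {b: mutual_information(h, m, b) for b in mi_bins}
    n = len(h)
    boot_rmse, boot_r2 = [], []
    boot_mi = {b: [] for b in mi_bins}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        hb, mb = h[idx], m[idx]
        boot_rmse.append(np.sqrt(np.mean((hb - mb) ** 2)))
        if hb.std() > 0 and mb.std() > 0:
            boot_r2.append(stats.pearsonr(hb, mb)[0] ** 2)
        for b in mi_bins:
            boot_mi[b].append(mutual_information(hb, mb, b))
    ci = lambda a: (float(np.percentile(a, 2.5)),
                    float(np.percentile(a, 97.5))) if len(a) else None
    return SimilarityReport(
        rmse=rmse, pearson_r2=r2, mutual_information=mi,
        rmse_ci=ci(boot_rmse), r2_ci=ci(boot_r2),
        mi_ci={b: ci(v) for b, v in boot_mi.items()}, r_undefined=r_undef)


def sign_test(scores_a, scores_b):
    """Exact two-tailed binomial sign test on paired scores.

    Ties are dropped (and counted).  Returns (p_value, n_positive,
    n_negative, n_ties) where positive means a > b.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    ties = int((d == 0).sum())
    n = pos + neg
    if n == 0:
        raise ValueError("all pairs tied; sign test undefined")
    p = stats.binomtest(pos, n, 0.5, alternative="two-sided").pvalue
    return float(p), pos, neg, ties


# ---------------------------------------------------------------------
# permutation interaction test
# ---------------------------------------------------------------------

def _interaction_stat(cells: np.ndarray) -> float:
    """Sum of squared interaction terms of the participant-mean table.

    cells: (participants, directions, offsets).
    interaction_ij = t_ij - mu_i. - mu_.j + mu_..
    """
    t = cells.mean(axis=0)
    mu_dir = t.mean(axis=1, keepdims=True)
    mu_off = t.mean(axis=0, keepdims=True)
    inter = t - mu_dir - mu_off + t.mean()
    return float((inter ** 2).sum())


def permutation_interaction(table: ThresholdTable, n_perm: int = 10000,
                            rng: np.random.Generator | None = None) -> dict:
    """Permutation test for a direction x offset interaction.

    Condition labels are permuted within participant; p uses the
    (b + 1) / (n + 1) estimator.  Returns observed statistic, p-value
    and the null distribution.
    """
    rng = rng or np.random.default_rng(0)
    cells = table.thresholds
    n_sub, n_dir, n_off = cells.shape
    ncell = n_dir * n_off
    observed = _interaction_stat(cells)
    flat = cells.reshape(n_sub, ncell)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = np.argsort(rng.random((n_sub, ncell)), axis=1)
        shuf = np.take_along_axis(flat, perm, axis=1)
        null[k] = _interaction_stat(shuf.reshape(n_sub, n_dir, n_off))
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {"observed": observed, "p_value": float(p), "null": null}


def permutation_type1_rate(n_runs: int = 500, n_perm: int = 500,
                           n_subjects: int = 33, shape=(2, 3),
                           alpha: float = 0.05, main_effect_sd: float = 0.0,
                           rng: np.random.Generator | None = None) -> float:
    """Empirical false-positive rate of the interaction test under an
    additive (no-interaction) null with iid noise.

    With main_effect_sd = 0 the cell labels are exchangeable within
    participant and the test is exact (rate ~ alpha).  Non-zero main
    effects leak into the permuted interaction statistic and make the
    plain label permutation conservative (rate below alpha).
    """
    rng = rng or np.random.default_rng(0)
    rejections = 0
    for _ in range(n_runs):
        cells = rng.normal(0, 1, (n_subjects,) + shape)
        if main_effect_sd > 0:
            cells += rng.normal(0, main_effect_sd, shape[0])[None, :, None]
            cells += rng.normal(0, main_effect_sd, shape[1])[None, None, :]
        res = permutation_interaction(ThresholdTable(cells), n_perm=n_perm,
                                      rng=rng)
        rejections += res["p_value"] <= alpha
    return rejections / n_runs


def permutation_power(n_runs: int = 200, n_perm: int = 500,
                      n_subjects: int = 33, shape=(2, 3),
                      effect: float = 2.0, noise_sd: float = 1.0,
                      alpha: float = 0.05,
                      rng: np.random.Generator | None = None) -> float:
    """Detection rate for a planted interaction of `effect` x noise SD."""
    rng = rng or np.random.default_rng(0)
    hits = 0
    for _ in range(n_runs):
        cells = rng.normal(0, noise_sd, (n_subjects,) + shape)
        cells[:, 0, -1] += effect * noise_sd
        res = permutation_interaction(ThresholdTable(cells), n_perm=n_perm,
                                      rng=rng)
        hits += res["p_value"] <= alpha
    return hits / n_runs


# ---------------------------------------------------------------------
# stage-of-selection analysis
# ---------------------------------------------------------------------

def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel().astype(np.float64), b.ravel().astype(np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def stage_selection(model, quads) -> dict:
    """Per-stage target-mixture and distractor-mixture correlations.

    `quads` is a list of (cue_coch, target_coch, distractor_coch,
    mix_coch) arrays, each (C, F, T).  Each signal is passed through the
    attended forward pass with the same cue (matching the target talker);
    per stage, Pearson r is computed over the flattened activations and
    averaged over quads.  Degenerate (zero-variance) stages yield NaN and
    are skipped in the averages.
    """
    from ._autograd import Tensor
    names = model.net.stage_names()
    tr = {n: [] for n in names}
    dr = {n: [] for n in names}
    for cue, tgt, dis, mixc in quads:
        cue_t = Tensor(cue[None])
        recs = {}
        for key, sig in (("target", tgt), ("distractor", dis),
                         ("mixture", mixc)):
            rec = []
            model.forward_attend(cue_t, Tensor(sig[None]), record=rec)
            recs[key] = {name: t.data[0] for name, t in rec}
        for name in names:
            tr[name].append(_flat_corr(recs["target"][name],
                                       recs["mixture"][name]))
            dr[name].append(_flat_corr(recs["distractor"][name],
                                       recs["mixture"][name]))
    out = {}
    for name in names:
        out[name] = {
            "target_r": float(np.nanmean(tr[name])),
            "distractor_r": float(np.nanmean(dr[name])),
        }
        out[name]["gap"] = out[name]["target_r"] - out[name]["distractor_r"]
    return out
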