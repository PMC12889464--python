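"""Closed-loop triggering paradigm, as a simulation.

Units are split into fast-spiking (FS, trough-to-peak < 200 us) and
regular-spiking (RS) classes from the template waveforms. During each
trial's fixation period (up to 1 s), the FS-population firing rate is
evaluated every 50 ms; the first window exceeding 2 SDs above the
baseline mean triggers the stimulus, otherwise it is presented at the
end of fixation (non-triggered). Control trials bypass the rule with a
conventionally scheduled onset. The analysis compares pre-stimulus
(-100 to 0 ms) and evoked firing rates across conditions with
Mann-Whitney U tests; the normalized response (evoked / pre-stimulus)
excludes units with zero pre-stimulus activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_probe import RawRecording, SortedOutput
from .sortengine import sort_stream

__all__ = [
    "WaveformClass",
    "TriggerConfig",
    "classify_waveforms",
    "run_trigger_session",
    "analyze_prestim",
    "FS_WIDTH_CUT_US",
]

FS_WIDTH_CUT_US = 200.0


@dataclass
class WaveformClass:
    unit_id: int
    trough_to_peak_us: float
    label: str  # "FS" | "RS"

    def __post_init__(self):
        is_fs = np.isfinite(self.trough_to_peak_us) and (
            self.trough_to_peak_us < FS_WIDTH_CUT_US
        )
        if (self.label == "FS") != is_fs:
            raise ValueError("label inconsistent with the 200 us FS rule")


@dataclass
class TriggerConfig:
    baseline_window_ms: float = 100.0
    eval_window_ms: float = 50.0
    threshold_sd: float = 2.0
    fixation_max_s: float = 1.0

    def __post_init__(self):
        for name in ("baseline_window_ms", "eval_window_ms", "fixation_max_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def classify_waveforms(bank) -> list[WaveformClass]:
    """FS/RS split of bank templates by trough-to-peak width.

    Width = (post-trough peak sample - trough sample) on the
    maximum-amplitude channel, in microseconds at the bank's sampling
    rate. Strictly below 200 us is FS; monophasic templates (no positive
    peak after the trough) are RS with a warning.
    """
    import logging

    fs = bank.preproc.fs
    out = []
    for k in range(bank.n_templates):
        tpl = bank.templates[k]
        ch = int(np.argmax(np.abs(tpl).max(axis=0)))
        w = tpl[:, ch]
        trough = int(np.argmin(w))
        after = w[trough + 1 :]
        if len(after) == 0 or after.max() <= 0:
            logging.getLogger(__name__).warning(
                "template %d is monophasic; classifying as RS", k
            )
            width_us = float("inf")
        else:
            peak = trough + 1 + int(np.argmax(after))
            width_us = (peak - trough) / fs * 1e6
        label = "FS" if width_us < FS_WIDTH_CUT_US else "RS"
        out.append(WaveformClass(unit_id=k, trough_to_peak_us=width_us, label=label))
    return out


def _population_rate(times: np.ndarray, start: float, end: float, n_units: int) -> float:
    """Mean per-unit firing rate (Hz) of pooled spikes in [start, end) s."""
    n = np.count_nonzero((times >= start) & (times < end))
    return n / max(n_units, 1) / (end - start)


def run_trigger_session(
    recording_or_stream,
    bank,
    fs_units: list,
    config: TriggerConfig,
    trials_spec: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the firing-rate trigger rule over a session.

    ``recording_or_stream`` is a RawRecording (live-sorted here through
    ``sort_stream``) or an already sorted SortedOutput. ``fs_units`` are
    the FS-labeled cluster ids whose pooled rate drives the trigger.
    ``trials_spec`` needs columns ``fixation_start_s``, ``kind``
    ("closedloop" or "control") and ``direction_deg``; the baseline
    statistics are computed on windows before the first fixation.

    Returns the TrialTable: onset_sample, condition (triggered /
    non_triggered / control), trigger_latency_ms (triggered only) and
    direction_deg.
    """
    if len(fs_units) == 0:
        raise ValueError("fs_units must be nonempty")
    if isinstance(recording_or_stream, RawRecording):
        sorted_out = sort_stream(recording_or_stream, bank)
    elif isinstance(recording_or_stream, SortedOutput):
        sorted_out = recording_or_stream
    else:
        raise TypeError("expected RawRecording or SortedOutput")
    fs = sorted_out.fs
    fs_mask = np.isin(sorted_out.clusters, fs_units)
    fs_times_s = sorted_out.times[fs_mask] / fs
    n_fs = len(fs_units)

    first_fix = float(trials_spec["fixation_start_s"].min())
    bw = config.baseline_window_ms / 1e3
    edges = np.arange(0.0, first_fix - bw + 1e-12, bw)
    if len(edges) < 2:
        raise ValueError("baseline period before the first trial is too short")
    base_rates = np.array(
        [_population_rate(fs_times_s, e, e + bw, n_fs) for e in edges]
    )
    mu_b = float(base_rates.mean())
    sd_b = float(base_rates.std(ddof=1))
    if sd_b <= 1e-9 * max(mu_b, 1.0):
        raise ValueError(
            "baseline rate SD is zero; use a longer or noisier baseline epoch"
        )
    thr = mu_b + config.threshold_sd * sd_b

    rng = np.random.default_rng(seed)
    ew = config.eval_window_ms / 1e3
    n_windows = int(round(config.fixation_max_s / ew))
    rows = []
    for _, tr in trials_spec.iterrows():
        t0 = float(tr["fixation_start_s"])
        if tr.get("kind", "closedloop") == "control":
            onset_s = t0 + rng.uniform(0.2, config.fixation_max_s)
            rows.append((onset_s, "control", np.nan, tr["direction_deg"]))
            continue
        onset_s = t0 + config.fixation_max_s
        condition = "non_triggered"
        latency = np.nan
        for i in range(n_windows):
            ws, we = t0 + i * ew, t0 + (i + 1) * ew
            if _population_rate(fs_times_s, ws, we, n_fs) > thr:
                onset_s = we  # stimulus follows the detected window
                condition = "triggered"
                latency = (we - t0) * 1e3
                break
        rows.append((onset_s, condition, latency, tr["direction_deg"]))
    table = pd.DataFrame(
        rows, columns=["onset_s", "condition", "trigger_latency_ms", "direction_deg"]
    )
    table["onset_sample"] = (table["onset_s"] * fs).round().astype(np.int64)
    return table[
        ["onset_sample", "condition", "trigger_latency_ms", "direction_deg"]
    ]


def analyze_prestim(
    sorted_out,
    trials: pd.DataFrame,
    classes: list,
    fs: float | None = None,
    prestim_window_ms: tuple = (-100.0, 0.0),
    response_window_ms: tuple = (50.0, 250.0),
) -> dict:
    """Per-unit, per-condition pre-stimulus and evoked firing rates.

    ``sorted_out`` is a SortedOutput or a dict of unit -> spike-time
    arrays (then ``fs`` is required). The normalized response is
    evoked / pre-stimulus; units with zero mean pre-stimulus rate in a
    condition are excluded from the normalized summary only. Condition
    contrasts use two-sided Mann-Whitney U on per-trial pre-stimulus
    rates; the FS vs RS contrast compares normalized triggered minus
    non-triggered differences across units.
    """
    if isinstance(sorted_out, SortedOutput):
        trains = sorted_out.trains()
        fs = sorted_out.fs
    else:
        trains = sorted_out
        if fs is None:
            raise ValueError("fs required when passing raw train dicts")
    conditions = [c for c in trials["condition"].unique()]
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    for c in conditions:
        n = (trials["condition"] == c).sum()
        if n < 5:
            raise ValueError(f"condition {c!r} has only {n} trials (need >= 5)")

    p0, p1 = prestim_window_ms
    r0, r1 = response_window_ms
    pre_win_s = (p1 - p0) / 1e3
    resp_win_s = (r1 - r0) / 1e3
    label_of = {cl.unit_id: cl.label for cl in classes}

    unit_rows = []
    trial_rates: dict[tuple, np.ndarray] = {}
    for uid, t in trains.items():
        t = np.asarray(t)
        for cond in conditions:
            onsets = trials.loc[trials["condition"] == cond, "onset_sample"].to_numpy()
            pre = np.array(
                [
                    np.count_nonzero((t >= o + p0 * fs / 1e3) & (t < o + p1 * fs / 1e3))
                    / pre_win_s
                    for o in onsets
                ]
            )
            evoked = np.array(
                [
                    np.count_nonzero((t >= o + r0 * fs / 1e3) & (t < o + r1 * fs / 1e3))
                    / resp_win_s
                    for o in onsets
                ]
            )
            trial_rates[(uid, cond, "pre")] = pre
            trial_rates[(uid, cond, "evoked")] = evoked
            mean_pre = float(pre.mean())
            mean_ev = float(evoked.mean())
            unit_rows.append(
                {
                    "unit_id": uid,
                    "label": label_of.get(uid, "RS"),
                    "condition": cond,
                    "prestim_hz": mean_pre,
                    "evoked_hz": mean_ev,
                    "normalized": mean_ev / mean_pre if mean_pre > 0 else np.nan,
                }
            )
    units_df = pd.DataFrame(unit_rows)

    # condition contrasts on pooled per-trial pre-stimulus rates (FS units)
    fs_ids = [uid for uid in trains if label_of.get(uid, "RS") == "FS"]
    contrasts = {}
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1 :]:
            for which in ("pre", "evoked"):
                x = np.concatenate(
                    [trial_rates[(u, c1, which)] for u in fs_ids]
                ) if fs_ids else np.array([])
                ytr = np.concatenate(
                    [trial_rates[(u, c2, which)] for u in fs_ids]
                ) if fs_ids else np.array([])
                if len(x) and len(ytr) and (x.std() + ytr.std() > 0):
                    stat, p = stats.mannwhitneyu(x, ytr, alternative="two-sided")
                else:
                    stat, p = np.nan, 1.0
                contrasts[f"fs_{which}_{c1}_vs_{c2}"] = {
                    "statistic": float(stat), "p_value": float(p),
                }

    # FS vs RS contrast of normalized triggered - non-triggered differences
    fs_rs = {"p_value": np.nan}
    if {"triggered", "non_triggered"} <= set(conditions):
        piv = units_df.pivot_table(
            index=["unit_id", "label"], columns="condition", values="normalized"
        ).reset_index()
        for col in ("triggered", "non_triggered"):
            if col not in piv.columns:
                piv[col] = np.nan
        piv = piv.dropna(subset=["triggered", "non_triggered"])
        piv["norm_diff"] = piv["triggered"] - piv["non_triggered"]
        fsd = piv.loc[piv["label"] == "FS", "norm_diff"].to_numpy()
        rsd = piv.loc[piv["label"] == "RS", "norm_diff"].to_numpy()
        if len(fsd) >= 2 and len(rsd) >= 2:
            _, p = stats.mannwhitneyu(fsd, rsd, alternative="two-sided")
            fs_rs = {"p_value": float(p), "n_fs": len(fsd), "n_rs": len(rsd)}
    return {"units": units_df, "contrasts": contrasts, "fs_vs_rs_normalized": fs_rs}
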