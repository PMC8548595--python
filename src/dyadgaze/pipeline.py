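"""End-to-end pipeline: recording -> events -> trial labels -> inference.

Stages (each independently callable):

1. ``segment_session`` — per trial and actor, AOI look sequences from
   gaze and the point onset from the initiator's hand kinematics.
2. ``classify_trials`` — congruency, overt attention, eye contact and
   SRT per trial, with per-trial exclusion reasons.
3. ``screen`` (via :func:`dyadgaze.trials.screen_trials`) — study-level
   screening (errors, low calibration).
4. ``analyze`` — mixed-model fits per stratum plus LRT.

``run_pipeline`` composes them, starting from a simulation or from
recording files on disk, and writes a self-describing report bundle.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import scene
from .config import RunConfig
from .events import NoOnsetError, detect_point_onset, segment_gaze_trial
from .geometry import AoiLayout
from .inference import InsufficientDataError, fit_srt_model
from .simulate import generate_study
from .trials import (classify_congruency, compute_srt, detect_eye_contact,
                     flag_overt_attention, handshake_end, screen_trials)

log = logging.getLogger("dyadgaze")

__all__ = ["segment_session", "classify_trials", "analyze", "run_pipeline"]


def _layout_for(agent: int, cfg: RunConfig, partner_hand: pd.DataFrame | None,
                gaze_times: np.ndarray) -> AoiLayout:
    """AOI layout for classifying ``agent``'s gaze over a trial.

    The partner's hand box is re-posed per gaze frame from the fingertip
    stream; the wrist is reconstructed by stepping back from the
    fingertip toward the partner's shoulder (the recording carries only
    the fingertip marker).
    """
    other = 1 - agent
    a = cfg.aoi
    partner_wrist = partner_fingertip = None
    if partner_hand is not None and len(partner_hand) >= 2:
        th = partner_hand["time_s"].to_numpy(dtype=float)
        tip = np.column_stack([
            np.interp(gaze_times, th, partner_hand[c].to_numpy(dtype=float))
            for c in ("pos_x", "pos_y", "pos_z")])
        shoulder = scene.agent_nasion(other) - np.array([0.0, 0.25, 0.0])
        back = tip - shoulder
        n = np.linalg.norm(back, axis=1, keepdims=True)
        back = np.where(n > 1e-9, back / np.maximum(n, 1e-12), [[0.0, 0.0, 1.0]])
        partner_wrist = tip - a.hand_length_m * back
        partner_fingertip = tip
    return AoiLayout(
        partner_nasion=scene.agent_nasion(other),
        cube_centers=scene.cube_centers(a.cube_spacing_m),
        face_radius_deg=a.face_radius_deg,
        cube_size=a.cube_size_m,
        start_centers=np.stack([scene.start_center(0), scene.start_center(1)]),
        start_size=a.start_size_m,
        body_center=scene.body_center(other),
        body_size=tuple(a.body_size_m),
        partner_wrist=partner_wrist,
        partner_fingertip=partner_fingertip,
        hand_length=a.hand_length_m,
        hand_cross=a.hand_cross_m,
    )


def segment_session(recording: pd.DataFrame, metadata: pd.DataFrame,
                    cfg: RunConfig) -> dict:
    """Segment one session into per-trial looks and point onsets.

    Returns ``{trial_id: {"looks": {actor: [LookEvent]}, "onset":
    PointOnset | None, "onset_error": str | None}}``.
    """
    out = {}
    rec = recording
    for _, meta in metadata.iterrows():
        trial = int(meta["trial"])
        init = int(meta["initiator"])
        target = int(meta["target_cube"])
        tr_rows = rec[rec["trial_id"] == trial]
        looks = {}
        for agent in (0, 1):
            gaze = tr_rows[(tr_rows["actor_id"] == agent) & (tr_rows["stream"] == "gaze")]
            partner_hand = tr_rows[(tr_rows["actor_id"] == 1 - agent)
                                   & (tr_rows["stream"] == "hand")]
            layout = _layout_for(agent, cfg, partner_hand,
                                 gaze["time_s"].to_numpy(dtype=float))
            looks[agent] = segment_gaze_trial(
                gaze, layout, actor=agent,
                min_look_duration=cfg.events.min_look_duration_s,
                gap_bridge=cfg.events.gap_bridge_s)
        hand = tr_rows[(tr_rows["actor_id"] == init) & (tr_rows["stream"] == "hand")]
        target_pos = scene.cube_centers(cfg.aoi.cube_spacing_m)[target]
        onset = None
        onset_error = None
        try:
            onset = detect_point_onset(
                hand["time_s"].to_numpy(dtype=float),
                hand[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float),
                target_pos, fraction=cfg.events.onset_fraction,
                speed_mode=cfg.events.speed_mode,
                arrival_radius=cfg.events.arrival_radius_m)
        except (NoOnsetError, ValueError) as exc:
            onset_error = str(exc)
            log.warning("trial %s: no onset (%s)", trial, exc)
        out[trial] = {"looks": looks, "onset": onset, "onset_error": onset_error}
    return out


def events_table(segmented: dict) -> pd.DataFrame:
    """Tidy event table (one row per look / onset) for CSV export."""
    rows = []
    for trial, seg in segmented.items():
        for agent, looks in seg["looks"].items():
            for lk in looks:
                rows.append(dict(trial=trial, actor=agent, event_type="look",
                                 aoi=lk.aoi, start_t=lk.start_t, end_t=lk.end_t,
                                 onset_t=np.nan))
        if seg["onset"] is not None:
            rows.append(dict(trial=trial, actor=-1, event_type="point_onset",
                             aoi="", start_t=np.nan, end_t=np.nan,
                             onset_t=seg["onset"].onset_t))
    return pd.DataFrame(rows).sort_values(["trial", "event_type", "start_t"],
                                          ignore_index=True)


def classify_trials(segmented: dict, metadata: pd.DataFrame,
                    cfg: RunConfig) -> pd.DataFrame:
    """Derive the per-trial analysis variables from segmented events."""
    rows = []
    for _, meta in metadata.iterrows():
        trial = int(meta["trial"])
        init = int(meta["initiator"])
        resp = int(meta["responder"])
        target = int(meta["target_cube"])
        pair = meta["pair"]
        seg = segmented[trial]
        row = dict(pair=f"p{pair}", subject=f"p{pair}s{resp}",
                   trial=f"t{trial}", initiator=init, responder=resp,
                   target_cube=target, validity=float(meta["validity"]),
                   response_correct=bool(meta["response_correct"]),
                   onset_t=np.nan, congruency="uncharacterizable",
                   overt_attention=False, eye_contact=False,
                   srt_ms=np.nan, exclusion="none")
        if seg["onset"] is None:
            row["exclusion"] = "no_onset"
            rows.append(row)
            continue
        onset = seg["onset"]
        row["onset_t"] = onset.onset_t
        looks_i = seg["looks"][init]
        looks_r = seg["looks"][resp]
        row["congruency"] = classify_congruency(
            looks_i, onset, target, face_after_nontarget=cfg.face_after_nontarget)
        row["overt_attention"] = flag_overt_attention(
            looks_r, onset, window_s=cfg.overt_window_s)
        hs_end = handshake_end(looks_i, looks_r, float(meta["trial_start"]))
        row["eye_contact"] = detect_eye_contact(
            looks_i, looks_r, hs_end, onset,
            min_overlap_s=cfg.eye_contact_min_overlap_s)
        srt, reason = compute_srt(looks_r, onset, target,
                                  anticipatory_ms=cfg.srt.anticipatory_ms,
                                  too_slow_ms=cfg.srt.too_slow_ms)
        row["srt_ms"] = np.nan if srt is None else srt
        row["exclusion"] = reason
        rows.append(row)
    return pd.DataFrame(rows)


def descriptive_rates(table: pd.DataFrame) -> dict:
    """Participant-averaged descriptive percentages (congruent gaze,
    overt attention, eye contact), computed on screened trials.

    Congruent-gaze and overt-attention rates average per-participant
    percentages over initiator (resp. responder) identities; eye contact
    averages the per-pair percentage of trials, mirroring how the study
    reports these descriptives.
    """
    t = table[table["exclusion"].isin(["none", "anticipatory", "too_slow",
                                       "no_target_look"])]
    cong = []
    for (_, _), g in t.groupby(["pair", "initiator"]):
        char = g[g["congruency"].isin(["congruent", "incongruent"])]
        if len(char):
            cong.append(100.0 * (char["congruency"] == "congruent").mean())
    overt = []
    for (_, _), g in t.groupby(["pair", "responder"]):
        if len(g):
            overt.append(100.0 * g["overt_attention"].mean())
    eye = []
    for _, g in t.groupby("pair"):
        if len(g):
            eye.append(100.0 * g["eye_contact"].mean())
    return {
        "congruent_gaze_pct": {"mean": float(np.mean(cong)) if cong else np.nan,
                               "sd": float(np.std(cong, ddof=1)) if len(cong) > 1 else np.nan},
        "overt_attention_pct": {"mean": float(np.mean(overt)) if overt else np.nan,
                                "sd": float(np.std(overt, ddof=1)) if len(overt) > 1 else np.nan},
        "eye_contact_pct": {"mean": float(np.mean(eye)) if eye else np.nan,
                            "sd": float(np.std(eye, ddof=1)) if len(eye) > 1 else np.nan},
    }


def analyze(table: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fit the congruency model on each configured stratum.

    The transformation is selected once, on all analysable SRTs, and the
    same transform is then used in every stratified refit so that the
    strata stay comparable on one scale.
    """
    transform = cfg.stats.transform
    if transform == "auto":
        from .inference import select_transform

        ok = table[(table["exclusion"] == "none")
                   & table["congruency"].isin(["congruent", "incongruent"])]
        srts = ok["srt_ms"].to_numpy(dtype=float)
        srts = srts[np.isfinite(srts)]
        if len(srts) >= 10:
            transform = select_transform(srts)
    results = {}
    for stratum in cfg.stats.strata:
        try:
            res = fit_srt_model(table, stratum=stratum, transform=transform)
            results[stratum] = res.to_dict()
        except InsufficientDataError as exc:
            results[stratum] = {"error": str(exc)}
            log.warning("stratum %s: %s", stratum, exc)
    return results


def run_pipeline(cfg: RunConfig, out_dir, recording: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None) -> dict:
    """Full pipeline; simulates a study when no recording is supplied.

    Writes ``analysis_table.csv``, ``screening.json``, ``model.json``
    and ``report.md`` into ``out_dir`` and returns the bundle as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = None
    if recording is None:
        sim = cfg.sim.replace(seed=cfg.seed, cube_spacing=cfg.aoi.cube_spacing_m)
        recording, truth = generate_study(sim)
        metadata = dio.trial_metadata(truth)
        dio.write_recording(recording, out_dir / "recording.csv.gz")
        dio.write_truth(truth, out_dir / "ground_truth.csv")
    if metadata is None:
        raise ValueError("metadata is required when supplying a recording")

    tables = []
    for pair, meta_p in metadata.groupby("pair"):
        rec_p = recording[recording["pair_id"] == pair]
        seg = segment_session(rec_p, meta_p, cfg)
        tables.append(classify_trials(seg, meta_p, cfg))
        log.info("pair %s: segmented and classified %d trials", pair, len(meta_p))
    table = pd.concat(tables, ignore_index=True)
    table, screening = screen_trials(table, validity_cutoff=cfg.validity_cutoff)
    rates = descriptive_rates(table)
    models = analyze(table, cfg)

    table.to_csv(out_dir / "analysis_table.csv", index=False, float_format="%.9g")
    dio.write_json(screening, out_dir / "screening.json")
    dio.write_json({"models": models, "rates": rates, "config": cfg.to_dict()},
                   out_dir / "model.json")
    report = _markdown_report(screening, rates, models, cfg)
    (out_dir / "report.md").write_text(report)
    return {"table": table, "screening": screening, "rates": rates,
            "models": models, "truth": truth, "report": report}


def _fmt_model(name: str, m: dict) -> str:
    if "error" in m:
        return f"- **{name}**: not estimable ({m['error']})\n"
    d = m["descriptives"]
    lines = [f"- **{name}** (n={m['n_obs']}, transform={m['transform']['family']}, "
             f"random: {m['random_structure']}):",
             f"  b = {m['b']:.3f}, SE = {m['se']:.3f}, t = {m['t']:.3f}, "
             f"p = {m['p']:.4f} [{m['df_method']}]",
             f"  LRT: chi2({m['lrt_df']}) = {m['chi2']:.2f}, p = {m['lrt_p']:.4f}, "
             f"evidence ratio exp(dLL) = {m['evidence_ratio']:.2f}"]
    for cls in ("congruent", "incongruent"):
        if cls in d:
            lines.append(f"  {cls}: M = {d[cls]['mean_ms']:.2f} ms, "
                         f"SD = {d[cls]['sd_ms']:.2f} ms (n={d[cls]['n']})")
    return "\n".join(lines) + "\n"


def _markdown_report(screening: dict, rates: dict, models: dict, cfg: RunConfig) -> str:
    r = ["# Dyadic joint-attention analysis report", "",
         "## Screening", "",
         f"- trials: {screening['n_total']} total, {screening['n_retained']} retained, "
         f"{screening['n_excluded']} excluded",
         f"- by reason: {screening['by_reason']}", "",
         "## Descriptive rates (participant means)", ""]
    for key, label in (("congruent_gaze_pct", "initiator gaze-point congruency"),
                       ("overt_attention_pct", "responder overt attention at onset"),
                       ("eye_contact_pct", "eye contact before onset")):
        v = rates[key]
        r.append(f"- {label}: {v['mean']:.1f}% (SD {v['sd']:.1f}%)"
                 if np.isfinite(v["mean"]) else f"- {label}: n/a")
    r += ["", "## Congruency effect on saccadic reaction time", ""]
    for name, m in models.items():
        r.append(_fmt_model(name, m))
    r += ["", "## Configuration", "",
          f"- onset fraction: {cfg.events.onset_fraction}; speed mode: {cfg.events.speed_mode}",
          f"- face radius: {cfg.aoi.face_radius_deg} deg; "
          f"min look: {cfg.events.min_look_duration_s*1000:.0f} ms; "
          f"gap bridge: {cfg.events.gap_bridge_s*1000:.0f} ms",
          f"- SRT bounds: ({cfg.srt.anticipatory_ms:.0f}, {cfg.srt.too_slow_ms:.0f}] ms; "
          f"validity cutoff: {cfg.validity_cutoff}",
          f"- seed: {cfg.seed}", ""]
    return "\n".join(r)
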