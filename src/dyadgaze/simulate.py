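"""Generative model of dyadic joint-attention sessions with ground truth.

Emulates the task structure of the study the package analyses: each pair
completes 54 trials (27 with each participant initiating), three cubes
30 cm apart, the initiator sees three even numbers with the highest on
the target cube and points at it, and the responder follows the point.

The generator scripts, per trial:

* a mutual-gaze handshake that starts the trial,
* an initiator scanpath over the cubes whose final pre-point fixation
  realises a drawn congruency class (congruent / incongruent /
  uncharacterizable target->face sequence),
* a minimum-jerk pointing reach whose 5 %-of-peak-speed crossing is the
  ground-truth point onset,
* a responder who is on the initiator's face at onset with probability
  ``p_overt_attention`` and whose first target look lags onset by a
  saccadic reaction time (SRT) drawn from a normal model with nested
  random intercepts (pair > subject, plus trial),
* optional mutual eye contact, anticipatory / slow responses, pointing
  errors and low-calibration trials to exercise every screening rule.

Gaze is emitted at 60 Hz and hand position at 120 Hz.  Identical seeds
reproduce identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scene
from .geometry import normalize

__all__ = [
    "SimConfig",
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "minimum_jerk_onset_offset",
    "generate_point_trajectory",
    "generate_schedule",
    "generate_session",
    "simulate_trial_table",
]

GAZE_RATE = 60.0
HAND_RATE = 120.0


@dataclass
class SimConfig:
    """Generative parameters for a simulated study.

    Probabilities are per trial; durations in seconds, SRTs in ms.
    ``p_congruent`` is the probability that a *characterizable* trial is
    congruent; ``p_uncharacterizable`` is the probability of the
    target->face sequence for which congruency is undefined.
    """

    n_pairs: int = 1
    trials_per_pair: int = 54
    p_congruent: float = 0.51
    p_uncharacterizable: float = 0.10
    p_overt_attention: float = 0.60
    p_eye_contact: float = 0.0408
    srt_base: float = 675.0  # mean responder SRT on incongruent trials, ms
    srt_congruency_benefit: float = 56.0  # subtracted when congruent AND overt
    srt_sd: float = 150.0  # residual SD, ms
    subject_sd: float = 50.0
    pair_sd: float = 40.0
    trial_sd: float = 25.0
    gaze_noise_deg: float = 0.5
    p_error: float = 0.02  # point lands on a non-target cube
    p_low_validity: float = 0.0  # calibration validity drawn below the 0.90 cutoff
    p_anticipatory: float = 0.0  # SRT drawn in (0, 100] ms
    p_too_slow: float = 0.0  # SRT drawn in (3000, 4000] ms
    fixation_min_s: float = 0.15
    fixation_max_s: float = 0.40
    handshake_s: float = 0.40
    point_duration_s: float = 0.80
    cube_spacing: float = 0.30
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("p_congruent", "p_uncharacterizable", "p_overt_attention",
                     "p_eye_contact", "p_error", "p_low_validity",
                     "p_anticipatory", "p_too_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("srt_sd", "subject_sd", "pair_sd", "trial_sd", "gaze_noise_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trials_per_pair % 2 != 0:
            raise ValueError("trials_per_pair must be even (roles are counterbalanced)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.point_duration_s <= 0:
            raise ValueError("point_duration_s must be > 0")
        return self

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# minimum-jerk kinematics

def minimum_jerk_position(start, end, tau):
    """Minimum-jerk position at normalized time ``tau`` in [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return start + np.multiply.outer(s, end - start).reshape(s.shape + start.shape)


def minimum_jerk_speed(distance: float, duration: float, tau):
    """Speed profile ``|d| * 30 tau^2 (1-tau)^2 / T``; peak 1.875 |d|/T at tau=0.5."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return distance * 30.0 * tau**2 * (1 - tau) ** 2 / duration


def minimum_jerk_onset_offset(duration: float, fraction: float = 0.05) -> float:
    """Time after movement start when speed first reaches ``fraction`` of peak.

    Solves ``30 tau^2 (1-tau)^2 = fraction * 1.875`` for the first root in
    (0, 0.5); closed form via the quadratic in ``tau (1-tau)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    c = np.sqrt(fraction * 1.875 / 30.0)  # tau (1 - tau) = c
    disc = 1.0 - 4.0 * c
    if disc < 0:
        raise ValueError("fraction too large for a crossing before peak")
    tau = (1.0 - np.sqrt(disc)) / 2.0
    return float(tau * duration)


def generate_point_trajectory(start, target, onset_t: float, duration: float,
                              rate: float = HAND_RATE, t0: float = 0.0,
                              t_end: float | None = None,
                              jitter_m: float = 0.0, rng=None) -> pd.DataFrame:
    """Fingertip time series: rest at ``start``, minimum-jerk reach, rest at target.

    ``onset_t`` is the movement *start* time (speed identically zero
    before it).  Samples run from ``t0`` to ``t_end`` (default: movement
    end) on the native hand-tracking grid.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if t_end is None:
        t_end = onset_t + duration
    n = int(np.floor((t_end - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    tau = (t - onset_t) / duration
    pos = minimum_jerk_position(np.asarray(start, float), np.asarray(target, float), tau)
    if jitter_m > 0 and rng is not None:
        pre = t < onset_t
        pos[pre] += rng.normal(0.0, jitter_m, size=(int(pre.sum()), 3))
    return pd.DataFrame({"time_s": t, "pos_x": pos[:, 0], "pos_y": pos[:, 1], "pos_z": pos[:, 2]})


# ---------------------------------------------------------------------------
# trial schedule

def generate_schedule(config: SimConfig, rng: np.random.Generator | None = None,
                      pair_id: int = 0) -> pd.DataFrame:
    """Balanced trial schedule for one pair.

    Each participant initiates exactly half the trials; within each
    participant's initiator trials the target is spread across the three
    cubes as evenly as divisibility allows.  The initiator display holds
    three even numbers with the '6' on the target; the responder sees a
    mix of odd and even numbers.  Trial order is randomized under the
    config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.trials_per_pair
    half = n // 2
    rows = []
    for initiator in (0, 1):
        targets = np.tile(np.arange(3), half // 3 + 1)[:half]
        rng.shuffle(targets)
        for tgt in targets:
            # initiator sees {2,4,6} with 6 on the target cube
            even = np.array([2, 4])
            rng.shuffle(even)
            init_numbers = np.empty(3, dtype=int)
            init_numbers[tgt] = 6
            init_numbers[[i for i in range(3) if i != tgt]] = even
            resp_numbers = rng.choice([1, 2, 3, 4, 5], size=3, replace=False)
            if np.all(resp_numbers % 2):  # all odd: swap one in for a mixed display
                resp_numbers[rng.integers(3)] = rng.choice([2, 4])
            rows.append(dict(initiator=initiator, target_cube=int(tgt),
                             init_numbers=",".join(map(str, init_numbers)),
                             resp_numbers=",".join(map(str, resp_numbers))))
    order = rng.permutation(n)
    sched = pd.DataFrame([rows[i] for i in order])
    sched.insert(0, "trial", np.arange(n))
    sched.insert(0, "pair", pair_id)
    sched["responder"] = 1 - sched["initiator"]
    return sched


# ---------------------------------------------------------------------------
# session generation

def _jittered_dir(origin, point, noise_deg, rng):
    """Unit directions origin->point with isotropic angular jitter (degrees)."""
    d = normalize(np.asarray(point, float) - np.asarray(origin, float))
    d = np.atleast_2d(d)
    if noise_deg > 0:
        # small-angle jitter: add a tangential Gaussian perturbation
        sd = np.radians(noise_deg)
        perp = rng.normal(0.0, sd, size=(len(d), 3))
        perp -= d * np.einsum("ij,ij->i", perp, d)[:, None]
        d = normalize(d + perp)
    return d


class _GazeScript:
    """Ordered list of (start, end, aim_point, aoi_hint) segments for one agent."""

    def __init__(self):
        self.segments: list[tuple[float, float, np.ndarray, str]] = []

    def add(self, start: float, end: float, point, hint: str):
        if end > start:
            self.segments.append((start, end, np.asarray(point, float), hint))

    def face_intervals(self):
        return [(s, e) for s, e, _, h in self.segments if h == "face"]

    def sample(self, t: np.ndarray, neutral_point) -> np.ndarray:
        """Aim points per gaze sample; gaps fall back to the neutral point."""
        pts = np.tile(np.asarray(neutral_point, float), (len(t), 1))
        for s, e, p, _ in self.segments:
            m = (t >= s) & (t < e)
            pts[m] = p
        return pts


def _draw_dwell(rng, cfg):
    return rng.uniform(cfg.fixation_min_s, cfg.fixation_max_s)


def _srt_model_draw(rng, cfg, congruent: bool, overt: bool,
                    b_pair: float, b_subj: float, b_trial: float) -> float:
    """One SRT draw (ms) from the nested random-intercept model.

    Random intercepts: pair, subject (nested in pair) and trial index
    (shared across pairs, capturing order effects).  Draws are truncated
    at 120 ms — a valid overt response cannot precede that.
    """
    mean = cfg.srt_base - (cfg.srt_congruency_benefit if (congruent and overt) else 0.0)
    srt = mean + b_pair + b_subj + b_trial + rng.normal(0.0, cfg.srt_sd)
    return max(srt, 120.0)


def generate_session(config: SimConfig, pair_id: int = 0,
                     rng: np.random.Generator | None = None,
                     trial_effects: np.ndarray | None = None):
    """Simulate one pair's session.

    Returns
    -------
    recording : DataFrame
        Long-form recording (gaze 60 Hz + hand 120 Hz rows for both
        agents) in the canonical on-disk schema.
    truth : DataFrame
        Per-trial ground truth: roles, target, true onset time, true
        congruency / overt-attention / eye-contact labels, the embedded
        SRT (ms, quantized to the gaze grid actually emitted), validity
        and response correctness.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sched = generate_schedule(config, rng, pair_id=pair_id)

    b_pair = rng.normal(0.0, config.pair_sd)
    b_subj = rng.normal(0.0, config.subject_sd, size=2)
    if trial_effects is None:
        trial_effects = rng.normal(0.0, config.trial_sd, size=config.trials_per_pair)

    cubes = scene.cube_centers(config.cube_spacing)
    nasion = [scene.agent_nasion(0), scene.agent_nasion(1)]
    eye = [scene.agent_eye_origin(0), scene.agent_eye_origin(1)]
    neutral = [scene.neutral_gaze_point(0), scene.neutral_gaze_point(1)]

    gaze_rows = []
    hand_rows = []
    truth_rows = []
    t_cursor = 0.0

    for _, tr in sched.iterrows():
        init = int(tr["initiator"])
        resp = 1 - init
        target = int(tr["target_cube"])

        # ----- draw the trial's behavioural contingencies
        u = rng.random()
        if u < config.p_uncharacterizable:
            cong_class = "uncharacterizable"
        elif rng.random() < config.p_congruent:
            cong_class = "congruent"
        else:
            cong_class = "incongruent"
        overt = rng.random() < config.p_overt_attention
        want_eye_contact = rng.random() < config.p_eye_contact
        is_error = rng.random() < config.p_error
        validity = rng.uniform(0.50, 0.89) if rng.random() < config.p_low_validity else 1.0

        pointed = target
        if is_error:
            pointed = int(rng.choice([c for c in range(3) if c != target]))

        # ----- initiator scanpath
        t0 = t_cursor
        script_i = _GazeScript()
        script_r = _GazeScript()
        hs_end = t0 + config.handshake_s
        script_i.add(t0, hs_end, nasion[resp], "face")
        script_r.add(t0, hs_end, nasion[init], "face")

        t = hs_end
        scan = list(rng.permutation(3))
        nontarget = int(rng.choice([c for c in range(3) if c != target]))
        if cong_class == "congruent":
            if scan[-1] != target:
                scan.append(target)
        elif cong_class == "incongruent":
            if scan[-1] != nontarget:
                scan.append(nontarget)
        for c in scan[:-1]:
            d = _draw_dwell(rng, config)
            script_i.add(t, t + d, cubes[c], f"cube{c + 1}")
            t += d
        t_ec = None
        if want_eye_contact:
            # mid-search mutual face interval (>= 100 ms) before the final fixation
            t_ec = t
            d = 0.15
            script_i.add(t, t + d, nasion[resp], "face")
            script_r.add(t, t + d, nasion[init], "face")
            t += d

        final_dwell = max(_draw_dwell(rng, config), 0.30)
        if cong_class == "uncharacterizable":
            # target fixation then a face look that spans the point onset
            d = _draw_dwell(rng, config)
            script_i.add(t, t + d, cubes[target], f"cube{target + 1}")
            t += d
            script_i.add(t, t + final_dwell + config.point_duration_s,
                         nasion[resp], "face")
        else:
            last = scan[-1]
            script_i.add(t, t + final_dwell + config.point_duration_s,
                         cubes[last], f"cube{last + 1}")
        # movement starts a little into the final fixation so the 5 % crossing
        # falls safely inside it
        move_start = t + 0.10
        onset_true = move_start + minimum_jerk_onset_offset(config.point_duration_s)

        # ----- responder script
        srt_ms = _srt_model_draw(rng, config, cong_class == "congruent", overt,
                                 b_pair, b_subj[resp],
                                 trial_effects[int(tr["trial"])])
        if config.p_anticipatory > 0 and rng.random() < config.p_anticipatory:
            srt_ms = rng.uniform(20.0, 100.0)
        elif config.p_too_slow > 0 and rng.random() < config.p_too_slow:
            srt_ms = rng.uniform(3050.0, 4000.0)

        # pre-onset: responder scans cubes (naive to the target's role);
        # the scan fills around the scripted eye-contact interval so no
        # later segment ever overwrites it
        attend_start = onset_true - 0.30
        if t_ec is not None:
            attend_start = max(attend_start, t_ec + 0.15)

        def _fill_scans(t_from: float, t_to: float) -> None:
            while t_from < t_to - config.fixation_min_s:
                d = min(_draw_dwell(rng, config), t_to - t_from)
                c = int(rng.integers(3))
                script_r.add(t_from, t_from + d, cubes[c], f"cube{c + 1}")
                t_from += d

        if t_ec is not None:
            _fill_scans(hs_end, t_ec)
            _fill_scans(t_ec + 0.15, attend_start)
        else:
            _fill_scans(hs_end, attend_start)
        # saccade-to-target time: quantize to the gaze grid so the embedded
        # latency is exactly recoverable from the emitted samples
        t_sacc_raw = onset_true + srt_ms / 1000.0
        t_sacc = np.ceil((t_sacc_raw - t0) * GAZE_RATE - 1e-9) / GAZE_RATE + t0
        if overt:
            script_r.add(attend_start, t_sacc, nasion[init], "face")
        else:
            hold = int(rng.choice([c for c in range(3) if c != target]))
            script_r.add(attend_start, t_sacc, cubes[hold], f"cube{hold + 1}")
        look_dur = 0.40
        script_r.add(t_sacc, t_sacc + look_dur, cubes[target], f"cube{target + 1}")

        t_end = max(t_sacc + look_dur, move_start + config.point_duration_s) + 0.10

        # ----- ground-truth labels from the scripted intervals
        srt_true_ms = (t_sacc - onset_true) * 1000.0
        eye_contact_true = _mutual_overlap(script_i.face_intervals(),
                                           script_r.face_intervals(),
                                           hs_end, onset_true,
                                           min_overlap=1.0 / GAZE_RATE)
        truth_rows.append(dict(
            pair=pair_id, trial=int(tr["trial"]), initiator=init, responder=resp,
            target_cube=target, pointed_cube=pointed,
            onset_t=onset_true, congruency=cong_class,
            overt_attention=bool(overt), eye_contact=bool(eye_contact_true),
            srt_ms=srt_true_ms, validity=validity,
            response_correct=not is_error, trial_start=t0, trial_end=t_end,
        ))

        # ----- emit gaze samples (60 Hz) for both agents
        n_g = int(np.floor((t_end - t0) * GAZE_RATE)) + 1
        tg = t0 + np.arange(n_g) / GAZE_RATE
        for agent, script in ((init, script_i), (resp, script_r)):
            pts = script.sample(tg, neutral[agent])
            dirs = _jittered_dir(eye[agent], pts, config.gaze_noise_deg, rng)
            gaze_rows.append(pd.DataFrame({
                "time_s": tg, "pair_id": pair_id, "actor_id": agent, "stream": "gaze",
                "origin_x": eye[agent][0], "origin_y": eye[agent][1], "origin_z": eye[agent][2],
                "dir_x": dirs[:, 0], "dir_y": dirs[:, 1], "dir_z": dirs[:, 2],
                "pos_x": np.nan, "pos_y": np.nan, "pos_z": np.nan,
                "nasion_x": nasion[agent][0], "nasion_y": nasion[agent][1],
                "nasion_z": nasion[agent][2],
                "validity": 1.0, "trial_id": int(tr["trial"]),
            }))

        # ----- emit hand samples (120 Hz)
        start_pos = scene.start_center(init) + np.array([0.0, 0.025, 0.0])
        traj = generate_point_trajectory(start_pos, cubes[pointed] + np.array([0.0, 0.05, 0.0]),
                                         move_start, config.point_duration_s,
                                         rate=HAND_RATE, t0=t0, t_end=t_end)
        for agent in (init, resp):
            if agent == init:
                px, py, pz = traj["pos_x"], traj["pos_y"], traj["pos_z"]
                th = traj["time_s"]
            else:
                n_h = int(np.floor((t_end - t0) * HAND_RATE)) + 1
                th = t0 + np.arange(n_h) / HAND_RATE
                rest = scene.start_center(agent) + np.array([0.0, 0.025, 0.0])
                px = np.full(len(th), rest[0]); py = np.full(len(th), rest[1]); pz = np.full(len(th), rest[2])
            hand_rows.append(pd.DataFrame({
                "time_s": th, "pair_id": pair_id, "actor_id": agent, "stream": "hand",
                "origin_x": np.nan, "origin_y": np.nan, "origin_z": np.nan,
                "dir_x": np.nan, "dir_y": np.nan, "dir_z": np.nan,
                "pos_x": np.asarray(px), "pos_y": np.asarray(py), "pos_z": np.asarray(pz),
                "nasion_x": nasion[agent][0], "nasion_y": nasion[agent][1],
                "nasion_z": nasion[agent][2],
                "validity": 1.0, "trial_id": int(tr["trial"]),
            }))

        t_cursor = t_end + 0.50  # inter-trial interval

    recording = pd.concat(gaze_rows + hand_rows, ignore_index=True)
    recording = recording.sort_values(["actor_id", "stream", "time_s"], kind="stable",
                                      ignore_index=True)
    truth = pd.DataFrame(truth_rows).merge(
        sched[["trial", "init_numbers", "resp_numbers"]], on="trial")
    return recording, truth


def _mutual_overlap(ints_a, ints_b, lo: float, hi: float, min_overlap: float) -> bool:
    """True if two interval sets overlap by >= min_overlap within (lo, hi)."""
    for sa, ea in ints_a:
        for sb, eb in ints_b:
            s = max(sa, sb, lo)
            e = min(ea, eb, hi)
            if e - s >= min_overlap - 1e-12:
                return True
    return False


def generate_study(config: SimConfig):
    """Simulate ``config.n_pairs`` independent sessions; concatenates outputs.

    Trial-index random effects are drawn once for the whole study and
    shared across pairs (they model order effects common to every
    session); pair and subject effects are per-session.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    trial_rng = np.random.default_rng(ss.spawn(1)[0])
    trial_effects = trial_rng.normal(0.0, config.trial_sd, size=config.trials_per_pair)
    recs, truths = [], []
    for pair_id, child in enumerate(ss.spawn(config.n_pairs)):
        rng = np.random.default_rng(child)
        rec, truth = generate_session(config, pair_id=pair_id, rng=rng,
                                      trial_effects=trial_effects)
        recs.append(rec)
        truths.append(truth)
    return pd.concat(recs, ignore_index=True), pd.concat(truths, ignore_index=True)


def simulate_trial_table(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-trial analysis rows directly from the distributional model.

    This is the same SRT model :func:`generate_session` embeds in its
    streams (congruency class, overt attention, nested pair > subject and
    trial random intercepts), without synthesising raw gaze/hand data.
    Used for inference calibration and parameter-recovery studies where
    only the trial-level table matters.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b_trial = rng.normal(0.0, config.trial_sd, size=config.trials_per_pair)
    rows = []
    for pair in range(config.n_pairs):
        b_pair = rng.normal(0.0, config.pair_sd)
        b_subj = rng.normal(0.0, config.subject_sd, size=2)
        for trial in range(config.trials_per_pair):
            resp = trial % 2  # alternating roles; responder identity
            u = rng.random()
            if u < config.p_uncharacterizable:
                cong = "uncharacterizable"
            elif rng.random() < config.p_congruent:
                cong = "congruent"
            else:
                cong = "incongruent"
            overt = rng.random() < config.p_overt_attention
            srt = _srt_model_draw(rng, config, cong == "congruent", overt,
                                  b_pair, b_subj[resp], b_trial[trial])
            rows.append(dict(pair=f"p{pair}", subject=f"p{pair}s{resp}",
                             trial=f"t{trial}", congruency=cong,
                             overt_attention=overt, eye_contact=False,
                             srt_ms=srt, exclusion="none"))
    return pd.DataFrame(rows)
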