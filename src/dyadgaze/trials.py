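"""Per-trial behavioural labels and trial screening.

Implements the study's coding rules:

* **Gaze-point congruency** — the initiator's last cube-or-face look
  ending at (or spanning) the point onset determines the class:
  target cube -> congruent; non-target cube -> incongruent; face
  preceded by a target-cube look -> uncharacterizable (the target->face
  sequence, for which congruency is undefined).  Looks to hand, body or
  start regions are transparent when scanning backwards.
* **Overt attention** — the responder has a face look containing the
  onset instant (closed right endpoint; optional look-back window).
* **Eye contact** — mutual face looks overlapping by at least one gaze
  sample, after the trial-start mutual-gaze handshake and before onset.
* **SRT** — start of the responder's first target-cube look after onset,
  minus the onset time; responses at or under 100 ms are excluded as
  anticipatory, responses over 3000 ms as too slow.
* **Screening** — error trials (point at a non-target cube) and trials
  whose eye-calibration validity fell strictly below 0.90 are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import LookEvent, PointOnset

__all__ = [
    "CONGRUENCY_CLASSES",
    "EXCLUSION_REASONS",
    "classify_congruency",
    "flag_overt_attention",
    "detect_eye_contact",
    "compute_srt",
    "screen_trials",
]

CONGRUENCY_CLASSES = ("congruent", "incongruent", "uncharacterizable")
EXCLUSION_REASONS = ("none", "error_response", "low_calibration", "no_onset",
                     "anticipatory", "too_slow", "no_target_look")

#: AOIs that participate in the congruency taxonomy; everything else is
#: skipped when scanning backwards from the onset.
_QUALIFYING = frozenset({"face", "cube1", "cube2", "cube3"})


def _cube_label(cube: int) -> str:
    return f"cube{cube + 1}"


def classify_congruency(initiator_looks: list[LookEvent], onset: PointOnset | float,
                        target_cube: int,
                        face_after_nontarget: str = "incongruent") -> str:
    """Congruency class of the initiator's pre-point gaze.

    ``face_after_nontarget`` controls the taxonomy edge where the final
    look is the partner's face but the preceding cube look was *not* the
    target: ``'incongruent'`` (default; the target->face sequence alone
    is uncharacterizable) or ``'uncharacterizable'``.
    """
    onset_t = onset.onset_t if isinstance(onset, PointOnset) else float(onset)
    if face_after_nontarget not in ("incongruent", "uncharacterizable"):
        raise ValueError("face_after_nontarget must be incongruent|uncharacterizable")
    qual = [lk for lk in initiator_looks
            if lk.aoi in _QUALIFYING and lk.start_t <= onset_t]
    if not qual:
        return "uncharacterizable"
    qual.sort(key=lambda lk: lk.start_t)
    last = qual[-1]
    if last.aoi != "face":
        return "congruent" if last.aoi == _cube_label(target_cube) else "incongruent"
    # final look is the face: inspect the preceding cube look
    cubes_before = [lk for lk in qual[:-1] if lk.aoi != "face"]
    if not cubes_before:
        return "uncharacterizable"
    if cubes_before[-1].aoi == _cube_label(target_cube):
        return "uncharacterizable"
    return face_after_nontarget


def flag_overt_attention(responder_looks: list[LookEvent], onset: PointOnset | float,
                         window_s: float = 0.0) -> bool:
    """True iff a responder face look contains the onset instant.

    Looks are half-open ``[start, end)`` but containment here uses a
    closed right endpoint, so a look ending exactly at the onset sample
    still counts.  ``window_s`` extends the test to any face look
    overlapping ``[onset - window_s, onset]``.
    """
    onset_t = onset.onset_t if isinstance(onset, PointOnset) else float(onset)
    for lk in responder_looks:
        if lk.aoi == "face" and lk.start_t <= onset_t and lk.end_t >= onset_t - window_s:
            return True
    return False


def detect_eye_contact(looks_a: list[LookEvent], looks_b: list[LookEvent],
                       search_start: float, onset: PointOnset | float,
                       min_overlap_s: float = 1.0 / 60.0) -> bool:
    """True iff the agents' face looks overlap within the search window.

    ``search_start`` is the end of the trial-start mutual-gaze handshake
    (the first moment both agents have left each other's face AOI);
    counting the handshake itself would classify essentially every trial
    as eye contact.  The window closes at the point onset.
    """
    onset_t = onset.onset_t if isinstance(onset, PointOnset) else float(onset)
    fa = [(lk.start_t, lk.end_t) for lk in looks_a if lk.aoi == "face"]
    fb = [(lk.start_t, lk.end_t) for lk in looks_b if lk.aoi == "face"]
    for sa, ea in fa:
        for sb, eb in fb:
            s = max(sa, sb, search_start)
            e = min(ea, eb, onset_t)
            if e - s >= min_overlap_s - 1e-12:
                return True
    return False


def handshake_end(looks_a: list[LookEvent], looks_b: list[LookEvent],
                  trial_start: float) -> float:
    """First time after ``trial_start`` at which neither agent is on the
    partner's face; the eye-contact search window opens here."""
    ends = [trial_start]
    for looks in (looks_a, looks_b):
        for lk in looks:
            if lk.aoi == "face" and lk.start_t <= trial_start + 1e-9 < lk.end_t:
                ends.append(lk.end_t)
    return max(ends)


def compute_srt(responder_looks: list[LookEvent], onset: PointOnset | float,
                target_cube: int, anticipatory_ms: float = 100.0,
                too_slow_ms: float = 3000.0) -> tuple[float | None, str]:
    """Saccadic reaction time in ms, or an exclusion reason.

    Returns ``(srt_ms, 'none')`` for a valid response, else
    ``(None, reason)`` with reason in {anticipatory, too_slow,
    no_target_look}.  The SRT is measured to the start of the first
    responder look at the target cube whose interval extends past the
    onset; a target look already under way at (or restarted within
    ``anticipatory_ms`` of) the onset is anticipatory.
    """
    onset_t = onset.onset_t if isinstance(onset, PointOnset) else float(onset)
    tgt = _cube_label(target_cube)
    cand = sorted((lk for lk in responder_looks if lk.aoi == tgt and lk.end_t > onset_t),
                  key=lambda lk: lk.start_t)
    if not cand:
        return None, "no_target_look"
    srt_ms = (cand[0].start_t - onset_t) * 1000.0
    if srt_ms <= anticipatory_ms:
        return None, "anticipatory"
    if srt_ms > too_slow_ms:
        return None, "too_slow"
    return srt_ms, "none"


def screen_trials(records: pd.DataFrame, validity_cutoff: float = 0.90) -> tuple[pd.DataFrame, dict]:
    """Apply the study's screening rules to a trial-record table.

    Expects columns ``pair, trial, response_correct, validity`` plus an
    ``exclusion`` column carrying per-trial reasons already assigned by
    the labelling stage ('none' where nothing applied).  Error responses
    and low calibration take precedence over downstream reasons.  The
    returned table keeps all rows with the final ``exclusion`` column
    set; the report itemizes counts per reason and per pair.  Screening
    is idempotent.
    """
    out = records.copy()
    if "exclusion" not in out.columns:
        out["exclusion"] = "none"
    excl = out["exclusion"].to_numpy(dtype=object)
    low_cal = out["validity"].to_numpy(dtype=float) < validity_cutoff
    error = ~out["response_correct"].to_numpy(dtype=bool)
    excl[low_cal] = "low_calibration"
    excl[error] = "error_response"  # highest precedence
    out["exclusion"] = excl
    retained = out[out["exclusion"] == "none"]
    report = {
        "n_total": int(len(out)),
        "n_retained": int(len(retained)),
        "n_excluded": int((out["exclusion"] != "none").sum()),
        "by_reason": {r: int((out["exclusion"] == r).sum())
                      for r in EXCLUSION_REASONS
                      if r != "none" and (out["exclusion"] == r).any()},
        "by_pair": {
            str(p): {r: int(c) for r, c in g["exclusion"].value_counts().items() if r != "none"}
            for p, g in out.groupby("pair")
        },
        "validity_cutoff": validity_cutoff,
    }
    assert report["n_retained"] + report["n_excluded"] == report["n_total"]
    return out, report
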