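"""Canonical positions of the shared scene (metres, y-up, origin at table centre).

The layout mirrors the physical set-up the simulator emulates: two agents
seated across a 1.5 x 1.15 m table, three 10 cm task cubes in a row along
x at the table midline, 30 cm apart, and a 5 cm start cube near each
agent's right hand.  The tabletop surface is the y = 0 plane.
"""

from __future__ import annotations

import numpy as np

TABLE_LENGTH = 1.50  # x extent
TABLE_WIDTH = 1.15  # z extent

#: z coordinate of each agent's seat side (agent 0 at negative z).
AGENT_Z = (-0.70, 0.70)
#: nasion height above the tabletop for a seated adult
NASION_HEIGHT = 0.45


def agent_nasion(agent: int) -> np.ndarray:
    return np.array([0.0, NASION_HEIGHT, AGENT_Z[agent]])


def agent_eye_origin(agent: int) -> np.ndarray:
    # cyclopean eye origin; coincides with the nasion in this model
    return agent_nasion(agent)


def cube_centers(spacing: float = 0.30) -> np.ndarray:
    """Three task cubes along x at the table midline, ``spacing`` apart."""
    return np.array([[-spacing, 0.05, 0.0], [0.0, 0.05, 0.0], [spacing, 0.05, 0.0]])


def start_center(agent: int) -> np.ndarray:
    """5 cm start cube near the agent's right hand."""
    side = -1.0 if agent == 0 else 1.0
    return np.array([0.20 * (-side), 0.025, 0.45 * side])


def body_center(agent: int) -> np.ndarray:
    """Centre of the agent's 40 x 60 cm torso AOI (hips to neck base)."""
    return np.array([0.0, 0.05, AGENT_Z[agent]])


def neutral_gaze_point(agent: int) -> np.ndarray:
    """An 'other' point: tabletop near the agent's own edge, off to the left."""
    side = -1.0 if agent == 0 else 1.0
    return np.array([0.55 * side, 0.0, 0.30 * side])
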