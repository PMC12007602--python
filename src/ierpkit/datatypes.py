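"""Core in-memory containers for the SEEG analysis pipeline.

Conventions: coordinates are millimetres in a right-handed space, time is
milliseconds relative to stimulus onset, epoch windows are half-open
[start, end). Amplitudes are in arbitrary (microvolt-like) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("smiling", "fearful", "neutral")
EMOTIONAL_CONDITIONS = ("smiling", "fearful")
HEMISPHERES = ("L", "R")

STIMULATION_CATEGORIES = (
    "sensorimotor",
    "interoceptive",
    "emotional",
    "language",
    "unspecific_subjective",
    "unresponsive",
)
BODY_DISTRICTS = ("face_mouth", "eye_neck", "hand_arm", "none")


@dataclass(frozen=True)
class Lead:
    """A single recording contact of a depth electrode."""

    lead_id: str
    position: np.ndarray  # (3,) mm
    hemisphere: str
    in_grey_matter: bool = True
    region_label: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(
                f"lead {self.lead_id!r}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"lead {self.lead_id!r}: hemisphere must be one of "
                f"{HEMISPHERES}, got {self.hemisphere!r}"
            )


class LeadSet:
    """Ordered collection of leads with a grey-matter-only view.

    Every analysis stage operates on :meth:`grey_matter`; white-matter
    contacts are retained only for bookkeeping.
    """

    def __init__(self, leads: list[Lead]):
        ids = [l.lead_id for l in leads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate lead ids")
        self._leads = list(leads)

    def __len__(self) -> int:
        return len(self._leads)

    def __iter__(self):
        return iter(self._leads)

    def __getitem__(self, lead_id: str) -> Lead:
        for l in self._leads:
            if l.lead_id == lead_id:
                return l
        raise KeyError(lead_id)

    @property
    def lead_ids(self) -> list[str]:
        return [l.lead_id for l in self._leads]

    @property
    def positions(self) -> np.ndarray:
        return np.array([l.position for l in self._leads])

    def grey_matter(self) -> "LeadSet":
        return LeadSet([l for l in self._leads if l.in_grey_matter])

    def with_regions(self, labels: dict[str, str | None]) -> "LeadSet":
        out = []
        for l in self._leads:
            out.append(
                Lead(
                    l.lead_id,
                    l.position,
                    l.hemisphere,
                    l.in_grey_matter,
                    labels.get(l.lead_id, l.region_label),
                )
            )
        return LeadSet(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lead_id": self.lead_ids,
                "x": [l.position[0] for l in self._leads],
                "y": [l.position[1] for l in self._leads],
                "z": [l.position[2] for l in self._leads],
                "hemisphere": [l.hemisphere for l in self._leads],
                "grey_matter": [l.in_grey_matter for l in self._leads],
                "region": [l.region_label for l in self._leads],
            }
        )


@dataclass
class EpochedRecording:
    """Per-lead, per-trial epoched voltage traces with condition labels.

    ``data`` is leads x trials x samples; sample *k* covers time
    ``epoch_window[0] + k * 1000 / sampling_rate`` ms.
    """

    lead_ids: list[str]
    conditions: np.ndarray  # (trials,) strings
    data: np.ndarray  # (leads, trials, samples)
    sampling_rate: float  # Hz
    epoch_window: tuple[float, float]  # (start_ms, end_ms), half-open

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        start, end = self.epoch_window
        if not start < 0 < end:
            raise ValueError("epoch_window must straddle stimulus onset")
        if self.data.ndim != 3:
            raise ValueError("data must be leads x trials x samples")
        n_leads, n_trials, n_samples = self.data.shape
        if n_leads != len(self.lead_ids):
            raise ValueError(
                f"data has {n_leads} leads but {len(self.lead_ids)} ids"
            )
        if n_trials != len(self.conditions):
            raise ValueError(
                f"data has {n_trials} trials but "
                f"{len(self.conditions)} condition labels"
            )
        expected = round((end - start) * self.sampling_rate / 1000.0)
        if n_samples != expected:
            raise ValueError(
                f"expected {expected} samples for window {self.epoch_window} "
                f"at {self.sampling_rate} Hz, got {n_samples}"
            )
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        start = self.epoch_window[0]
        step = 1000.0 / self.sampling_rate
        return start + step * np.arange(self.n_samples)

    def lead_index(self, lead_id: str) -> int:
        try:
            return self.lead_ids.index(lead_id)
        except ValueError:
            raise KeyError(lead_id) from None

    def trials(self, lead_id: str, condition: str | None = None) -> np.ndarray:
        """Trials x samples array for one lead, optionally one condition."""
        arr = self.data[self.lead_index(lead_id)]
        if condition is None:
            return arr
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return arr[self.conditions == condition]


@dataclass
class CorticalMesh:
    """Triangulated cortical surface with per-node hemisphere labels."""

    node_positions: np.ndarray  # (N, 3) mm
    triangles: np.ndarray  # (M, 3) int
    hemisphere: np.ndarray | None = None  # (N,) 'L'/'R'
    # explicit edges for constructions (e.g. a collinear strip) that carry
    # no non-degenerate triangles; (E, 2) int or None
    extra_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.node_positions.ndim != 2 or self.node_positions.shape[1] != 3:
            raise ValueError("node_positions must be N x 3")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be M x 3")
        n = len(self.node_positions)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValueError(
                f"triangle index out of range for {n}-node mesh"
            )
        if self.hemisphere is None:
            self.hemisphere = np.full(n, "L", dtype=object)
        else:
            self.hemisphere = np.asarray(self.hemisphere, dtype=object)
            if self.hemisphere.shape != (n,):
                raise ValueError("hemisphere must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    def edge_lengths(self) -> dict[tuple[int, int], float]:
        """Unique undirected edges with Euclidean lengths."""
        edges: dict[tuple[int, int], float] = {}

        def _add(i: int, j: int) -> None:
            key = (min(i, j), max(i, j))
            if key not in edges:
                edges[key] = float(
                    np.linalg.norm(
                        self.node_positions[i] - self.node_positions[j]
                    )
                )

        for tri in self.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                _add(int(tri[a]), int(tri[b]))
        if self.extra_edges is not None:
            for i, j in np.asarray(self.extra_edges, dtype=int):
                _add(int(i), int(j))
        return edges


@dataclass
class Parcellation:
    """Node -> region labelling plus a region lookup table.

    ``node_labels`` holds '' for unlabelled nodes. ``region_table`` is
    indexed by region name with columns ``hemisphere`` and ``display``.
    """

    node_labels: np.ndarray  # (N,) str, '' = unlabelled
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.node_labels = np.asarray(self.node_labels, dtype=object)
        used = {str(r) for r in self.node_labels if r}
        known = set(self.region_table.index.astype(str))
        missing = used - known
        if missing:
            raise ValueError(
                f"node labels reference unknown regions: {sorted(missing)}"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.region_table.index.astype(str))


@dataclass
class ConnectivityMatrix:
    """Region x region connection probabilities (afferent or efferent)."""

    regions: list[str]
    prob: np.ndarray  # (R, R) in [0, 1]
    direction: str  # 'afferent' | 'efferent'

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        r = len(self.regions)
        if self.prob.shape != (r, r):
            raise ValueError(
                f"probability matrix must be {r} x {r}, got {self.prob.shape}"
            )
        if np.any(~np.isfinite(self.prob)):
            raise ValueError("probabilities must be finite")
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.direction not in ("afferent", "efferent"):
            raise ValueError("direction must be 'afferent' or 'efferent'")


@dataclass(frozen=True)
class StimulationRecord:
    """Outcome of high-frequency (50 Hz) stimulation at one site."""

    site_id: str
    hemisphere: str
    current_ma: float
    category: str
    body_district: str | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"site {self.site_id!r}: hemisphere must be L or R"
            )
        if self.current_ma <= 0:
            raise ValueError(f"site {self.site_id!r}: current must be > 0 mA")
        if self.category not in STIMULATION_CATEGORIES:
            raise ValueError(
                f"site {self.site_id!r}: unknown category "
                f"{self.category!r}; expected one of {STIMULATION_CATEGORIES}"
            )
        if self.category == "sensorimotor":
            if self.body_district not in BODY_DISTRICTS:
                raise ValueError(
                    f"site {self.site_id!r}: sensorimotor records need a "
                    f"body district from {BODY_DISTRICTS}"
                )
        elif self.body_district not in (None, "", "none"):
            raise ValueError(
                f"site {self.site_id!r}: body district is only meaningful "
                "for sensorimotor responses"
            )


@dataclass
class SurfaceMap:
    """Per-node continuous map (sampling density or responsiveness %)."""

    map_kind: str  # 'density' | 'overall' | 'relative'
    values: np.ndarray  # (N,) density: leads/cm^2; others: percent
    mask: np.ndarray  # (N,) bool, True = displayable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.map_kind not in ("density", "overall", "relative"):
            raise ValueError(f"unknown map kind {self.map_kind!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must align")
        shown = self.values[self.mask]
        if self.map_kind in ("overall", "relative") and shown.size:
            if shown.min() < 0 or shown.max() > 100 + 1e-9:
                raise ValueError("percent maps must lie in [0, 100]")


@dataclass
class NodeNeighbourhood:
    """Geodesic disk around one node with logistic distance weights."""

    centre: int
    members: np.ndarray  # node indices, includes centre
    distances_mm: np.ndarray
    weights: np.ndarray  # in (0, 1]

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (
            len(self.members) == len(self.distances_mm) == len(self.weights)
        ):
            raise ValueError("neighbourhood arrays must align")
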