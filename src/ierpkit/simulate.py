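"""Synthetic study material: meshes, leads, epochs, connectivity, stimulation.

The generators reproduce the statistical structure the analysis chain
assumes — per-condition Gaussian-bump evoked deflections riding on
white-plus-1/f noise, leads scattered over a triangulated surface with a
fixed 7-node footprint each, and block-structured connection-probability
matrices — so every stage can be exercised without patient data. Every
generator is a pure function of its parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import (
    BODY_DISTRICTS,
    CONDITIONS,
    STIMULATION_CATEGORIES,
    ConnectivityMatrix,
    CorticalMesh,
    EpochedRecording,
    Lead,
    LeadSet,
    StimulationRecord,
)


@dataclass(frozen=True)
class EvokedSpec:
    """One condition's planted evoked deflection.

    ``width_ms`` is the full width at half maximum of the Gaussian bump.
    """

    condition: str
    amplitude: float
    peak_latency_ms: float
    width_ms: float = 100.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.peak_latency_ms <= 700:
            raise ValueError("peak latency must lie in (0, 700] ms")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: white Gaussian plus an optional 1/f component."""

    white_sd: float = 1.0
    pink_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.pink_sd < 0:
            raise ValueError("noise SDs must be >= 0")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def make_mesh(
    kind: str,
    n_nodes: int,
    spacing_mm: float = 1.0,
    seed: int = 0,
) -> CorticalMesh:
    """Build a synthetic surface.

    ``strip``: ``n_nodes`` collinear nodes at ``spacing_mm`` along x, chained
    by edges, so pairwise geodesics are exact chain sums (a collinear chain
    cannot carry non-degenerate triangles, so the strip is edge-connected
    with an empty triangle list). ``grid``: a flat rows x cols rectangle
    with ``n_nodes`` nodes (requires a composite ``n_nodes``). ``sphere``:
    a Fibonacci sphere triangulated by its convex hull, nodes at x < 0
    labelled hemisphere L.
    """
    if n_nodes < 3:
        raise ValueError("a mesh needs at least 3 nodes")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if kind == "strip":
        pos = np.zeros((n_nodes, 3))
        pos[:, 0] = spacing_mm * np.arange(n_nodes)
        edges = np.column_stack(
            [np.arange(n_nodes - 1), np.arange(1, n_nodes)]
        )
        return CorticalMesh(
            pos, np.empty((0, 3), dtype=int), extra_edges=edges
        )
    if kind == "grid":
        rows = _best_factor(n_nodes)
        if rows == 1:
            raise ValueError(
                f"grid needs a composite node count, got {n_nodes}"
            )
        cols = n_nodes // rows
        ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pos = np.column_stack(
            [
                spacing_mm * jj.ravel(),
                spacing_mm * ii.ravel(),
                np.zeros(n_nodes),
            ]
        )
        tris = []
        for i in range(rows - 1):
            for j in range(cols - 1):
                a = i * cols + j
                tris.append((a, a + 1, a + cols))
                tris.append((a + 1, a + cols + 1, a + cols))
        return CorticalMesh(pos, np.array(tris, dtype=int))
    if kind == "sphere":
        radius = spacing_mm * np.sqrt(n_nodes / (4 * np.pi))
        k = np.arange(n_nodes)
        golden = (1 + np.sqrt(5)) / 2
        z = 1 - 2 * (k + 0.5) / n_nodes
        theta = 2 * np.pi * k / golden
        r = np.sqrt(np.maximum(0.0, 1 - z**2))
        pos = radius * np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), z]
        )
        tris = ConvexHull(pos).simplices.astype(int)
        hemi = np.where(pos[:, 0] < 0, "L", "R").astype(object)
        return CorticalMesh(pos, tris, hemi)
    raise ValueError(f"unknown mesh kind {kind!r}")


def _best_factor(n: int) -> int:
    for r in range(int(np.sqrt(n)), 0, -1):
        if n % r == 0:
            return r
    return 1


# ---------------------------------------------------------------------------
# leads
# ---------------------------------------------------------------------------


def make_leads(
    mesh: CorticalMesh,
    n_leads: int,
    hemispheres: list[str] | None = None,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[LeadSet, dict[str, np.ndarray]]:
    """Scatter leads over mesh nodes and assign each its node footprint.

    Each lead sits on a distinct mesh node and is represented by the
    ``config.nodes_per_lead`` (default 7) nearest still-unclaimed nodes,
    so footprints are pairwise disjoint. Returns the lead set and the
    lead_id -> node-index assignment.
    """
    if n_leads < 1:
        raise ValueError("n_leads must be >= 1")
    k = config.nodes_per_lead
    if n_leads * k > mesh.n_nodes:
        raise ValueError(
            f"{n_leads} leads x {k} nodes exceed the {mesh.n_nodes}-node mesh"
        )
    rng = np.random.default_rng(seed)
    centres = rng.choice(mesh.n_nodes, size=n_leads, replace=False)
    claimed = np.zeros(mesh.n_nodes, dtype=bool)
    leads, assignment = [], {}
    for i, centre in enumerate(centres):
        lead_id = f"L{i:03d}"
        position = mesh.node_positions[centre]
        dists = np.linalg.norm(mesh.node_positions - position, axis=1)
        dists = np.where(claimed, np.inf, dists)
        nearest = np.argsort(dists, kind="stable")[:k]
        claimed[nearest] = True
        assignment[lead_id] = np.sort(nearest)
        if hemispheres is not None:
            hemi = hemispheres[i % len(hemispheres)]
        else:
            hemi = str(mesh.hemisphere[centre])
        leads.append(Lead(lead_id, position, hemi, in_grey_matter=True))
    return LeadSet(leads), assignment


# ---------------------------------------------------------------------------
# epoched recordings
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-SD 1/f-power noise along the last axis via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spectrum * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def evoked_waveform(
    spec: EvokedSpec, times_ms: np.ndarray
) -> np.ndarray:
    """Gaussian bump centred at the peak latency, zero before onset."""
    sigma = spec.width_ms / (2 * np.sqrt(2 * np.log(2)))
    wave = spec.polarity * spec.amplitude * np.exp(
        -0.5 * ((times_ms - spec.peak_latency_ms) / sigma) ** 2
    )
    return np.where(times_ms > 0, wave, 0.0)


def simulate_epochs(
    leads: LeadSet,
    evoked: dict[str, dict[str, EvokedSpec]],
    noise: NoiseSpec,
    n_trials_per_condition: int = 54,
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: int = 0,
    sampling_rate: float = 1000.0,
    epoch_window: tuple[float, float] = (-200.0, 700.0),
) -> EpochedRecording:
    """Simulate epoched trials: noise plus each condition's planted bump.

    ``evoked`` maps lead_id -> condition -> EvokedSpec; omitted entries
    get no evoked component (noise only). Trial order is randomised.
    """
    if n_trials_per_condition < 2:
        raise ValueError("need at least 2 trials per condition")
    for lead_id, spec_map in evoked.items():
        for spec in spec_map.values():
            if not (
                config.analysis_window[0]
                < spec.peak_latency_ms
                <= config.analysis_window[1]
            ):
                raise ValueError(
                    f"lead {lead_id!r}: evoked latency "
                    f"{spec.peak_latency_ms} ms outside the analysis window "
                    f"{config.analysis_window}"
                )
    rng = np.random.default_rng(seed)
    lead_ids = leads.lead_ids
    n_samples = round(
        (epoch_window[1] - epoch_window[0]) * sampling_rate / 1000.0
    )
    times = epoch_window[0] + 1000.0 / sampling_rate * np.arange(n_samples)
    conditions = np.repeat(CONDITIONS, n_trials_per_condition).astype(object)
    rng.shuffle(conditions)
    n_trials = len(conditions)
    data = noise.white_sd * rng.standard_normal(
        (len(lead_ids), n_trials, n_samples)
    )
    if noise.pink_sd > 0:
        data += noise.pink_sd * _pink_noise(
            rng, (len(lead_ids), n_trials, n_samples)
        )
    for li, lead_id in enumerate(lead_ids):
        for condition, spec in evoked.get(lead_id, {}).items():
            wave = evoked_waveform(spec, times)
            data[li, conditions == condition] += wave
    return EpochedRecording(
        lead_ids=lead_ids,
        conditions=conditions,
        data=data,
        sampling_rate=sampling_rate,
        epoch_window=epoch_window,
    )


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------


def simulate_connectivity(
    regions: list[str],
    blocks: list[list[str]],
    p_within: float = 0.8,
    p_between: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction: str = "afferent",
) -> ConnectivityMatrix:
    """Block-structured probability matrix with clipped Gaussian noise."""
    if not 0 <= p_between < p_within <= 1:
        raise ValueError("need 0 <= p_between < p_within <= 1")
    seen: set[str] = set()
    for block in blocks:
        overlap = seen & set(block)
        if overlap:
            raise ValueError(f"overlapping blocks: {sorted(overlap)}")
        seen |= set(block)
    if seen != set(regions):
        raise ValueError("blocks must partition the region list")
    membership = {r: i for i, block in enumerate(blocks) for r in block}
    labels = np.array([membership[r] for r in regions])
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p_within, p_between).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        prob = prob + noise_sd * rng.standard_normal(prob.shape)
    return ConnectivityMatrix(
        regions=list(regions),
        prob=np.clip(prob, 0.0, 1.0),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# stimulation outcomes
# ---------------------------------------------------------------------------


def simulate_stimulation(
    n_sites: int,
    category_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> list[StimulationRecord]:
    """Random stimulation-outcome table with sensible category frequencies.

    Default frequencies follow the typical mapping-session mix: most sites
    unresponsive, sensorimotor next, the rest rare.
    """
    if category_probs is None:
        category_probs = {
            "unresponsive": 0.62,
            "sensorimotor": 0.18,
            "interoceptive": 0.05,
            "emotional": 0.04,
            "language": 0.04,
            "unspecific_subjective": 0.07,
        }
    unknown = set(category_probs) - set(STIMULATION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    cats = list(category_probs)
    p = np.array([category_probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    districts = [d for d in BODY_DISTRICTS if d != "none"]
    records = []
    for i in range(n_sites):
        category = cats[rng.choice(len(cats), p=p)]
        district = (
            districts[rng.choice(len(districts))]
            if category == "sensorimotor"
            else None
        )
        records.append(
            StimulationRecord(
                site_id=f"S{i:03d}",
                hemisphere="L" if rng.random() < 0.5 else "R",
                current_ma=float(rng.choice([1.0, 2.0, 3.0, 4.0])),
                category=category,
                body_district=district,
            )
        )
    return records
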