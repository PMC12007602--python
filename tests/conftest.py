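import numpy as np
import pytest

import ierpkit as ik


@pytest.fixture(scope="session")
def config():
    return ik.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def sphere_mesh():
    return ik.make_mesh("sphere", 200, 3.0, seed=1)


@pytest.fixture(scope="session")
def grid_mesh():
    return ik.make_mesh("grid", 100, 1.0, seed=0)


@pytest.fixture(scope="session")
def strip_mesh():
    return ik.make_mesh("strip", 30, 1.0)


@pytest.fixture(scope="session")
def cube_off(tmp_path_factory):
    """Unit-cube surface: 8 nodes, 12 triangles."""
    path = tmp_path_factory.mktemp("mesh") / "cube.off"
    verts = [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ]
    faces = [
        (0, 2, 1), (0, 3, 2), (4, 5, 6), (4, 6, 7),
        (0, 1, 5), (0, 5, 4), (2, 3, 7), (2, 7, 6),
        (1, 2, 6), (1, 6, 5), (3, 0, 4), (3, 4, 7),
    ]
    lines = ["OFF", f"{len(verts)} {len(faces)} 0"]
    lines += [f"{x} {y} {z}" for x, y, z in verts]
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def make_recording(
    n_leads=2,
    evoked=None,
    n_trials=20,
    white_sd=1.0,
    pink_sd=0.0,
    seed=0,
):
    """Small synthetic recording over free-standing leads."""
    leads = ik.LeadSet(
        [
            ik.Lead(f"L{i:03d}", np.array([float(i), 0.0, 0.0]), "L")
            for i in range(n_leads)
        ]
    )
    return ik.simulate_epochs(
        leads,
        evoked or {},
        ik.NoiseSpec(white_sd=white_sd, pink_sd=pink_sd),
        n_trials_per_condition=n_trials,
        seed=seed,
    )


@pytest.fixture()
def small_recording():
    return make_recording()
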