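import numpy as np
import pandas as pd
import pytest

from avidiet import fem, phylo, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    return phylo.read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def tree32():
    return synth.simulate_tree(synth.SynthConfig(seed=42, n_taxa=32))


def random_tree(seed: int, n_taxa: int) -> phylo.TimeTree:
    return synth.simulate_tree(synth.SynthConfig(seed=seed, n_taxa=n_taxa))


def rect_mesh(L, H, nx, ny, crossed=True, material="bone"):
    """Structured rectangle mesh; crossed diagonals improve bending response."""
    xs = np.linspace(0, L, nx + 1)
    ys = np.linspace(0, H, ny + 1)
    nodes = [(x, y) for y in ys for x in xs]

    def idx(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b, c, d = idx(i, j), idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)
            if crossed:
                m = len(nodes)
                nodes.append(((xs[i] + xs[i + 1]) / 2, (ys[j] + ys[j + 1]) / 2))
                tris += [(a, b, m), (b, c, m), (c, d, m), (d, a, m)]
            else:
                tris += [(a, b, c), (a, c, d)]
    return fem.PlaneMesh(np.array(nodes, dtype=float), np.array(tris), [material] * len(tris))


def cantilever_tip_deflection(nx, ny, L=20.0, H=1.0, P=1.0, E=1000.0, nu=0.3):
    """Solve an end-loaded cantilever; returns (fem deflection, Timoshenko oracle)."""
    mesh = rect_mesh(L, H, nx, ny, crossed=True)
    ys = np.linspace(0, H, ny + 1)
    left = [j * (nx + 1) for j in range(ny + 1)]
    right = [j * (nx + 1) + nx for j in range(ny + 1)]
    fixed = {n: (True, True) for n in left}
    loads = {}
    for j in range(ny):
        seg = ys[j + 1] - ys[j]
        for n in (right[j], right[j + 1]):
            fx, fy = loads.get(n, (0.0, 0.0))
            loads[n] = (fx, fy - P * seg / H / 2)
    case = fem.LoadCase(extra_loads=loads, extra_fixed=fixed)
    res = fem.solve(mesh, {"bone": fem.Material(E=E, nu=nu)}, case)
    tip = right[ny // 2]
    # Timoshenko beam with plane-strain effective modulus
    Eeff = E / (1 - nu ** 2)
    G = E / (2 * (1 + nu))
    I = H ** 3 / 12
    kappa = 5.0 / 6.0
    oracle = -(P * L ** 3 / (3 * Eeff * I) + P * L / (kappa * G * H))
    return res.displacements[tip, 1], oracle


def solve_jaw(guild: str, seed: int, rham: float = 0.2, ref_area: float = 100.0):
    """Build, load-scale and solve one synthetic jaw; returns (mesh, result)."""
    jw = synth.synth_jaw(guild, seed=seed)
    mesh, case = fem.build_jaw_model(jw["outline"], rham, jw["attach_point"],
                                     bite_point=jw["bite_point"],
                                     pin_point=jw["pin_point"])
    F = fem.scale_load(fem.base_load(), ref_area, mesh.total_area())
    case = fem.LoadCase.from_magnitude(case.load_node, F, fem.DEFAULT_ATTACH_ANGLE_DEG,
                                       case.pin_node, case.bite_node)
    res = fem.solve(mesh, {"bone": fem.BONE, "rhamphotheca": fem.RHAMPHOTHECA}, case)
    return mesh, res
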