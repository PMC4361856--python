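import numpy as np
import pytest

from memglyco.model_io import Frame, Topology, Trajectory
from memglyco.synthetic import csf114_helix


@pytest.fixture(scope="session")
def csf114():
    """(topology, frame) of the bundled 21-residue glycopeptide ideal helix."""
    return csf114_helix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_two_lipid_membrane() -> tuple[Topology, Frame]:
    """Toy membrane: two lipids with one P atom and two chain carbons each."""
    names, res_ids = [], []
    coords = []
    for lip in (1, 2):
        for name, xyz in (("P", [8.0 * lip, 0.0, 18.0]),
                          ("N", [8.0 * lip, 1.0, 20.0]),
                          ("C32", [8.0 * lip, 0.0, 15.0]),
                          ("C33", [8.0 * lip, 0.5, 13.8])):
            names.append(name)
            res_ids.append(lip)
            coords.append(xyz)
    n = len(names)
    top = Topology(
        names=np.array(names), elements=np.array([x[0] for x in names]),
        res_ids=np.array(res_ids), res_names=np.array(["DMP"] * n),
        chain_ids=np.array(["M"] * n), hetero=np.zeros(n, dtype=bool))
    return top, Frame(coordinates=np.array(coords))


@pytest.fixture()
def two_lipid_membrane():
    return make_two_lipid_membrane()


def single_bead_trajectory(points, topology_name="X") -> Trajectory:
    """One-atom trajectory visiting the given points (funnel-flag fixtures)."""
    points = np.asarray(points, dtype=float)
    top = Topology(
        names=np.array([topology_name]), elements=np.array(["C"]),
        res_ids=np.array([1]), res_names=np.array(["ALA"]),
        chain_ids=np.array(["P"]), hetero=np.array([False]))
    frames = [Frame(coordinates=p.reshape(1, 3)) for p in points]
    return Trajectory(topology=top, frames=frames)
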