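import numpy as np
import pytest

from microcolony.lineage import CellRecord, LineageTree, Observation


def obs(frame, time_h, x=0.0, y=0.0, atp=None, placeholder=False,
        f405=None, f488=None):
    return Observation(frame=frame, time_h=time_h, x_um=x, y_um=y,
                       fluor_405=f405, fluor_488=f488, atp_mM=atp,
                       placeholder=placeholder)


def make_tree(cells):
    """Build a LineageTree from {cell_id: (parent_id, [Observation, ...])}."""
    tree = LineageTree()
    for cid, (pid, observations) in cells.items():
        tree.cells[cid] = CellRecord(cell_id=cid, parent_id=pid,
                                     observations=list(observations))
    return tree


def synchronous_tree(generations, frames_per_cell=2, atp=3.0):
    """Binary tree dividing in lockstep, with geometry consistent with
    old-pole inheritance: daughter '0' is placed farther from the parent's
    birth site than daughter '1'."""
    tree = LineageTree()
    step = 1.0

    def add(cell_id, parent_id, gen, t0, pos, parent_birth_pos):
        obs_list = [obs(int(t0) + k, t0 + k, x=pos[0], y=pos[1], atp=atp)
                    for k in range(frames_per_cell)]
        tree.cells[cell_id] = CellRecord(cell_id=cell_id, parent_id=parent_id,
                                         observations=obs_list)
        if gen == generations:
            return
        away = np.array(pos) - np.array(parent_birth_pos)
        n = np.linalg.norm(away)
        away = away / n if n > 0 else np.array([1.0, 0.0])
        # rotate slightly so subtrees fan out instead of overlapping
        ang = 0.7 if cell_id.endswith("0") else -0.7
        c, s = np.cos(ang), np.sin(ang)
        away = np.array([c * away[0] - s * away[1], s * away[0] + c * away[1]])
        t1 = t0 + frames_per_cell
        far = np.array(pos) + step * away
        near = np.array(pos) + 0.25 * step * away
        add(cell_id + "0", cell_id, gen + 1, t1, tuple(far), pos)
        add(cell_id + "1", cell_id, gen + 1, t1, tuple(near), pos)

    add("r", None, 0, 0.0, (0.0, 0.0), (-1.0, 0.0))
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
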