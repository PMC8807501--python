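"""HDF5 checkpointing of the microscale internal state.

The inelastic strain lives only on the microscale, so multiscale runs store
its complete quadrature-point field for every RVE for the previous and the
current time step; no information is lost between steps and a run can resume
from the last accepted step.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = ["CheckpointStore"]


class CheckpointStore:
    """Hierarchical container of inelastic-strain fields keyed (rve_id, step).

    Layout: ``/rve_<id>/step_<n>`` holds the (n_elems, n_qp, 6) array.  Only
    the two most recent steps of each RVE are kept by default, mirroring the
    double-buffered previous/current state of the time integrator.
    """

    def __init__(self, path, keep_last: int = 2):
        self.path = Path(path)
        self.keep_last = keep_last

    def save(self, rve_id, step: int, eps_i: np.ndarray) -> None:
        with h5py.File(self.path, "a") as f:
            grp = f.require_group(f"rve_{rve_id}")
            name = f"step_{step}"
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=eps_i)
            if self.keep_last:
                steps = sorted(
                    int(k.split("_")[1]) for k in grp.keys() if k.startswith("step_")
                )
                for old in steps[: -self.keep_last]:
                    del grp[f"step_{old}"]

    def load(self, rve_id, step: int) -> np.ndarray:
        with h5py.File(self.path, "r") as f:
            return np.asarray(f[f"rve_{rve_id}/step_{step}"])

    def last_step(self, rve_id) -> int | None:
        with h5py.File(self.path, "r") as f:
            key = f"rve_{rve_id}"
            if key not in f:
                return None
            steps = [
                int(k.split("_")[1]) for k in f[key].keys() if k.startswith("step_")
            ]
            return max(steps) if steps else None
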