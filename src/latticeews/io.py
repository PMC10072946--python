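"""HDF5 containers for run datasets and featurized datasets.

One file per dataset.  Runs live under ``/runs/<id>`` with the raw field,
site mask, forcing trajectory and (for Ising runs) the bond coupling fields;
labels and seeds are attributes.  A JSON manifest of the generation
parameters is stored as a root attribute so every artifact is traceable to
its configuration.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import h5py
import numpy as np

from .indicators import FeatureSet
from .lattice import IsingRun
from .systems import FieldRun

__all__ = ["save_runs", "load_runs", "save_features", "load_features"]


def save_runs(path, runs: Sequence, manifest: Optional[dict] = None) -> None:
    """Write a collection of runs (Ising or real-valued) to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest or {})
        fh.attrs["n_runs"] = len(runs)
        grp = fh.create_group("runs")
        for i, run in enumerate(runs):
            g = grp.create_group(f"run_{i:05d}")
            # spins (int8) compress very well under gzip; real-valued noise
            # fields barely compress, so use the fast lzf filter there
            comp = "gzip" if run.field.dtype == np.int8 else "lzf"
            g.create_dataset("field", data=run.field, compression=comp, shuffle=True)
            g.create_dataset("mask", data=run.mask)
            g.create_dataset("forcing", data=run.forcing)
            if isinstance(run, IsingRun):
                g.create_dataset("couplings", data=run.couplings)
            g.attrs["label"] = run.label
            g.attrs["order"] = run.order
            g.attrs["system"] = getattr(run, "system", "ising")
            g.attrs["seed"] = int(run.seed)
            g.attrs["transition_index"] = (
                -1 if run.transition_index is None else int(run.transition_index)
            )


def load_runs(path) -> tuple[list, dict]:
    """Load runs saved by :func:`save_runs`; returns ``(runs, manifest)``."""
    runs: list = []
    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs.get("manifest", "{}"))
        for name in sorted(fh["runs"]):
            g = fh["runs"][name]
            idx = int(g.attrs["transition_index"])
            common = dict(
                mask=g["mask"][()].astype(bool),
                forcing=g["forcing"][()],
                label=str(g.attrs["label"]),
                transition_index=None if idx < 0 else idx,
                seed=int(g.attrs["seed"]),
            )
            if str(g.attrs["system"]) == "ising":
                runs.append(
                    IsingRun(
                        spins=g["field"][()].astype(np.int8),
                        couplings=g["couplings"][()],
                        order=str(g.attrs["order"]),
                        **common,
                    )
                )
            else:
                runs.append(
                    FieldRun(
                        field=g["field"][()],
                        system=str(g.attrs["system"]),
                        order=str(g.attrs["order"]),
                        **common,
                    )
                )
    return runs, manifest


def save_features(path, features: FeatureSet) -> None:
    """Write a featurized dataset (indicator series + labels) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(features.manifest)
        fh.attrs["channel_names"] = json.dumps(list(features.channel_names))
        fh.create_dataset("X", data=features.X.astype(np.float32), compression="gzip")
        fh.create_dataset("y", data=features.y)
        fh.create_dataset("orders", data=np.asarray(features.orders, dtype="S32"))
        fh.create_dataset("lengths", data=features.lengths)


def load_features(path) -> FeatureSet:
    with h5py.File(path, "r") as fh:
        return FeatureSet(
            X=fh["X"][()],
            y=fh["y"][()],
            orders=fh["orders"][()].astype("U32"),
            lengths=fh["lengths"][()],
            channel_names=tuple(json.loads(fh.attrs["channel_names"])),
            manifest=json.loads(fh.attrs["manifest"]),
        )
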