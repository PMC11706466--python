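"""HDF5 persistence for feature and coupling tensors."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .spis import CouplingTensor, PairIndex
from .univariate import UnivariateFeatureTensor

_STR = h5py.string_dtype()


def save_feature_tensor(tensor: UnivariateFeatureTensor, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=tensor.values)
        h5.create_dataset("feature_names", data=np.array(tensor.feature_names, dtype=_STR))
        h5.create_dataset("subjects", data=np.array(tensor.subjects, dtype=_STR))
        h5.create_dataset("region_labels", data=np.array(tensor.region_labels, dtype=_STR))
    return path


def load_feature_tensor(path: str | Path) -> UnivariateFeatureTensor:
    with h5py.File(path, "r") as h5:
        return UnivariateFeatureTensor(
            values=h5["values"][()],
            feature_names=tuple(s.decode() for s in h5["feature_names"][()]),
            subjects=[s.decode() for s in h5["subjects"][()]],
            region_labels=[s.decode() for s in h5["region_labels"][()]],
            missing_log=[],
        )


def save_coupling_tensors(tensors: list[CouplingTensor], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for t in tensors:
            grp = h5.create_group(t.spi_name)
            grp.create_dataset("values", data=t.values)
            grp.create_dataset("pairs", data=np.array(t.pair_index.pairs))
            grp.create_dataset("subjects", data=np.array(t.subjects, dtype=_STR))
            grp.attrs["directed"] = t.pair_index.directed
            grp.attrs["n_regions"] = t.pair_index.n_regions
    return path


def load_coupling_tensors(path: str | Path) -> list[CouplingTensor]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in h5:
            grp = h5[name]
            pidx = PairIndex(
                n_regions=int(grp.attrs["n_regions"]),
                directed=bool(grp.attrs["directed"]),
                pairs=tuple(map(tuple, grp["pairs"][()].tolist())),
            )
            out.append(
                CouplingTensor(
                    spi_name=name,
                    values=grp["values"][()],
                    pair_index=pidx,
                    subjects=[s.decode() for s in grp["subjects"][()]],
                )
            )
    return out
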