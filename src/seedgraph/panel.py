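"""Group time-series container and its on-disk tabular format.

A :class:`TimeSeriesPanel` holds one signal matrix (time x nodes) per
subject, all sharing the same node labels and sampling interval.  On disk a
panel is a directory of delimiter-separated files, one per subject
(rows = time points, columns = nodes, header = node labels), plus a YAML
sidecar ``panel.yaml`` with the sampling interval and the labels of the
designated noise regions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeSeriesPanel",
    "PanelFormatError",
    "read_panel",
    "write_panel",
]


class PanelFormatError(ValueError):
    """Raised when panel files on disk violate the format contract."""


@dataclasses.dataclass
class TimeSeriesPanel:
    """Per-subject node signals over time.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_nodes, n_timepoints)
        Signal values in arbitrary units.
    tr_seconds : float
        Sampling interval in seconds (the repetition time for BOLD data).
    node_ids : list of str
        Node labels, shared by all subjects.
    noise_region_ids : list of str
        Subset of ``node_ids`` designated as nuisance-measurement regions
        (used by CompCor-style correction); may be empty.
    """

    data: np.ndarray
    tr_seconds: float
    node_ids: list[str]
    noise_region_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (subjects, nodes, time), got shape {self.data.shape}"
            )
        if self.data.shape[2] < 2:
            raise ValueError("time axis must have length >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.node_ids)} node_ids for {self.data.shape[1]} nodes"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        unknown = set(self.noise_region_ids) - set(self.node_ids)
        if unknown:
            raise ValueError(f"noise_region_ids not in node_ids: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr_seconds

    def node_index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def subject(self, i: int) -> np.ndarray:
        """Signals of subject ``i`` as a (n_nodes, n_timepoints) view."""
        return self.data[i]

    def neural_node_ids(self) -> list[str]:
        """Node labels excluding the designated noise regions."""
        noise = set(self.noise_region_ids)
        return [n for n in self.node_ids if n not in noise]

    def select_nodes(self, keep: Sequence[str]) -> "TimeSeriesPanel":
        """Return a sub-panel restricted to ``keep`` (order preserved)."""
        idx = [self.node_index(n) for n in keep]
        keep_set = set(keep)
        return TimeSeriesPanel(
            data=self.data[:, idx, :].copy(),
            tr_seconds=self.tr_seconds,
            node_ids=list(keep),
            noise_region_ids=[n for n in self.noise_region_ids if n in keep_set],
        )

    def copy_with(self, data: np.ndarray) -> "TimeSeriesPanel":
        """Same metadata, new data array."""
        return TimeSeriesPanel(
            data=data,
            tr_seconds=self.tr_seconds,
            node_ids=list(self.node_ids),
            noise_region_ids=list(self.noise_region_ids),
        )


_SIDECAR = "panel.yaml"


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> Path:
    """Write a panel as one TSV per subject plus a YAML sidecar.

    Values are stored with 10 significant digits; the round trip is lossless
    to that precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = len(str(panel.n_subjects))
    for i in range(panel.n_subjects):
        df = pd.DataFrame(panel.data[i].T, columns=panel.node_ids)
        df.to_csv(path / f"subject-{i + 1:0{width}d}.tsv", sep="\t",
                  index=False, float_format="%.10g")
    meta = {
        "tr_seconds": float(panel.tr_seconds),
        "noise_region_ids": list(panel.noise_region_ids),
        "n_subjects": panel.n_subjects,
    }
    with open(path / _SIDECAR, "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_panel(path: str | Path) -> TimeSeriesPanel:
    """Read a panel directory written by :func:`write_panel`."""
    path = Path(path)
    meta_path = path / _SIDECAR
    if not meta_path.exists():
        raise PanelFormatError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    files = sorted(p for p in path.glob("subject-*.tsv"))
    if not files:
        raise PanelFormatError(f"no subject files found in {path}")
    frames = []
    node_ids: list[str] | None = None
    for f in files:
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as exc:  # noqa: BLE001 - reported as format error
            raise PanelFormatError(f"malformed subject file {f}: {exc}") from exc
        cols = list(df.columns)
        if node_ids is None:
            node_ids = cols
        elif cols != node_ids:
            raise PanelFormatError(
                f"inconsistent node set: {f.name} has columns {cols}, "
                f"expected {node_ids}"
            )
        frames.append(df.to_numpy(dtype=float).T)
    assert node_ids is not None
    return TimeSeriesPanel(
        data=np.stack(frames),
        tr_seconds=float(meta["tr_seconds"]),
        node_ids=node_ids,
        noise_region_ids=[str(n) for n in meta.get("noise_region_ids", [])],
    )
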