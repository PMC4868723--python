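"""Core in-memory container for a two-group metabolomics concentration table.

Concentrations are in μM; missing measurements (below LOD, failed QC, ...)
are represented as NaN in :attr:`MetabolomicsDataset.values` with the mask
exposed through :attr:`MetabolomicsDataset.missing_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PANELS = ("kit", "lipids")

#: label coding used everywhere in the package
TUMOR, CONTROL = 1, 0


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class MetabolomicsDataset:
    """Samples × metabolites concentration matrix with binary group labels.

    Parameters
    ----------
    sample_ids
        One identifier per row.
    labels
        Binary vector, 1 = tumor, 0 = control.
    metabolite_names
        One unique name per column.
    values
        Float matrix of concentrations (μM); NaN marks missing entries.
    panel
        Per-metabolite measurement panel, one of ``{"kit", "lipids"}``.
    """

    sample_ids: list[str]
    labels: np.ndarray
    metabolite_names: list[str]
    values: np.ndarray
    panel: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.panel is None:
            self.panel = np.array(["kit"] * len(self.metabolite_names))
        self.panel = np.asarray(self.panel, dtype=object)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DatasetError(
                f"row mismatch: {n} rows, {len(self.sample_ids)} sample ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.metabolite_names) != p:
            raise DatasetError(
                f"column mismatch: {p} columns, {len(self.metabolite_names)} names"
            )
        if len(set(self.metabolite_names)) != p:
            seen, dupes = set(), set()
            for name in self.metabolite_names:
                (dupes if name in seen else seen).add(name)
            raise DatasetError(f"duplicate metabolite names: {sorted(dupes)}")
        if len(self.panel) != p:
            raise DatasetError("panel vector length does not match column count")
        bad_panel = set(self.panel) - set(PANELS)
        if bad_panel:
            raise DatasetError(f"unknown panel values: {sorted(bad_panel)}")
        if not np.isin(self.labels, (TUMOR, CONTROL)).all():
            raise DatasetError("labels must be binary (1 = tumor, 0 = control)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite < 0).any():
            raise DatasetError("non-missing concentrations must be >= 0")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples × metabolites mask, True where missing."""
        return np.isnan(self.values)

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == TUMOR

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    # -- access helpers --------------------------------------------------
    def column_index(self, name: str) -> int:
        try:
            return self.metabolite_names.index(name)
        except ValueError:
            raise KeyError(f"unknown metabolite: {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        """Concentration vector of one metabolite (NaN at missing entries)."""
        return self.values[:, self.column_index(name)]

    def subset(self, names: list[str]) -> "MetabolomicsDataset":
        """New dataset restricted to the given metabolite columns, in order."""
        idx = [self.column_index(n) for n in names]
        return MetabolomicsDataset(
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            metabolite_names=[self.metabolite_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            panel=self.panel[idx].copy(),
        )

    def panel_subset(self, panel: str) -> "MetabolomicsDataset":
        """New dataset restricted to the metabolites of one panel."""
        if panel not in PANELS:
            raise DatasetError(f"unknown panel {panel!r}")
        names = [n for n, q in zip(self.metabolite_names, self.panel) if q == panel]
        return self.subset(names)

    def copy(self) -> "MetabolomicsDataset":
        return MetabolomicsDataset(
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            metabolite_names=list(self.metabolite_names),
            values=self.values.copy(),
            panel=self.panel.copy(),
        )
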