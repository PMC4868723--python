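"""Reading and writing metabolomics concentration tables.

Two tab-delimited UTF-8 files carry one dataset:

``<prefix>_values.tsv``
    A ``# panel`` comment line giving the per-metabolite panel, then a
    one-line header (``sample_id`` followed by the metabolite names), then
    one row per sample. Missing cells are serialized as ``NA``; the tokens
    ``""``, ``NA`` and ``<LOD`` are all parsed as missing.

``<prefix>_meta.tsv``
    Header ``sample_id\tgroup`` then one row per sample with group in
    ``{"tumor", "control"}`` (mapped to labels 1/0).

Metabolite names are treated as opaque strings; tabs are the only reserved
character (lipid nomenclature freely uses commas and colons).
"""

from __future__ import annotations

import os

import numpy as np

from .dataset import CONTROL, TUMOR, MetabolomicsDataset

MISSING_TOKENS = {"", "NA", "<LOD"}
_GROUP_TO_LABEL = {"tumor": TUMOR, "control": CONTROL}
_LABEL_TO_GROUP = {v: k for k, v in _GROUP_TO_LABEL.items()}


class DataLoadError(ValueError):
    """Raised on malformed or inconsistent input files."""


def _split_tsv(path: str) -> list[list[str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [line.rstrip("\r\n").split("\t") for line in fh if line.strip("\r\n")]


def read_dataset(values_path: str, meta_path: str) -> MetabolomicsDataset:
    """Load a dataset from a values table and a sample-metadata table.

    Raises
    ------
    DataLoadError
        On duplicate metabolite columns or on sample-ID mismatch between
        the two files (the offending IDs are named in the message).
    """
    rows = _split_tsv(values_path)
    panel_row = None
    if rows and rows[0][0].startswith("#"):
        if rows[0][0].lstrip("# ").lower() == "panel":
            panel_row = rows[0][1:]
        rows = rows[1:]
    if not rows:
        raise DataLoadError(f"{values_path}: empty values file")
    header = rows[0]
    names = header[1:]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DataLoadError(f"duplicate metabolite columns: {sorted(dupes)}")
    sample_ids: list[str] = []
    data = np.full((len(rows) - 1, len(names)), np.nan)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise DataLoadError(
                f"{values_path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        sample_ids.append(row[0])
        for j, tok in enumerate(row[1:]):
            if tok in MISSING_TOKENS:
                continue
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise DataLoadError(
                    f"{values_path}: cannot parse {tok!r} at row {i + 2}, "
                    f"column {names[j]!r}"
                ) from None

    meta_rows = _split_tsv(meta_path)
    if not meta_rows or meta_rows[0][:2] != ["sample_id", "group"]:
        raise DataLoadError(f"{meta_path}: expected header 'sample_id\\tgroup'")
    groups: dict[str, str] = {}
    for row in meta_rows[1:]:
        groups[row[0]] = row[1]

    missing_meta = [s for s in sample_ids if s not in groups]
    extra_meta = [s for s in groups if s not in set(sample_ids)]
    if missing_meta or extra_meta:
        parts = []
        if missing_meta:
            parts.append(f"samples without metadata: {missing_meta}")
        if extra_meta:
            parts.append(f"metadata without samples: {extra_meta}")
        raise DataLoadError("sample-ID mismatch; " + "; ".join(parts))

    labels = np.empty(len(sample_ids), dtype=int)
    for i, sid in enumerate(sample_ids):
        group = groups[sid]
        if group not in _GROUP_TO_LABEL:
            raise DataLoadError(f"unknown group {group!r} for sample {sid!r}")
        labels[i] = _GROUP_TO_LABEL[group]

    panel = None
    if panel_row is not None:
        if len(panel_row) != len(names):
            raise DataLoadError("panel comment line does not match column count")
        panel = np.array(panel_row, dtype=object)
    return MetabolomicsDataset(
        sample_ids=sample_ids,
        labels=labels,
        metabolite_names=names,
        values=data,
        panel=panel,
    )


def write_dataset(ds: MetabolomicsDataset, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>_values.tsv`` and ``<prefix>_meta.tsv``.

    Values are serialized with 17 significant digits so that
    ``read_dataset(*write_dataset(ds, p))`` reproduces ``ds`` exactly;
    missing cells become ``NA``.
    """
    values_path = f"{prefix}_values.tsv"
    meta_path = f"{prefix}_meta.tsv"
    parent = os.path.dirname(os.path.abspath(values_path))
    if not os.path.isdir(parent):
        raise OSError(f"output directory does not exist: {parent}")

    with open(values_path, "w", encoding="utf-8") as fh:
        fh.write("# panel\t" + "\t".join(map(str, ds.panel)) + "\n")
        fh.write("sample_id\t" + "\t".join(ds.metabolite_names) + "\n")
        for sid, row in zip(ds.sample_ids, ds.values):
            cells = ["NA" if np.isnan(v) else format(v, ".17g") for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")

    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}\t{_LABEL_TO_GROUP[int(lab)]}\n")
    return values_path, meta_path
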