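"""Readers and writers for the pipeline's file formats.

Tabular data travels as delimiter-sniffed CSV/TSV; gene sets as GMT;
pixel spectra as imzML (continuous mode, via pyimzml) with the pixels x
peaks matrix and pixel coordinates as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ProbeCountMatrix


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kw)


def read_probe_counts(path) -> ProbeCountMatrix:
    """Probe count table: columns probe_id, gene, is_negative, then one
    column per segment."""
    df = _read_table(path).set_index("probe_id")
    meta_cols = ["gene", "is_negative"]
    counts = df.drop(columns=meta_cols)
    return ProbeCountMatrix(
        counts=counts.astype(int),
        probe_to_gene=df["gene"],
        is_negative=df["is_negative"].astype(bool),
    )


def write_probe_counts(pcm: ProbeCountMatrix, path) -> None:
    out = pd.concat(
        [pcm.probe_to_gene.rename("gene"), pcm.is_negative.rename("is_negative"),
         pcm.counts], axis=1
    )
    out.index.name = "probe_id"
    out.to_csv(path)


def read_segment_meta(path) -> pd.DataFrame:
    meta = _read_table(path)
    return meta.set_index("segment_id", drop=False)


def write_expression_tsv(expr_values: pd.DataFrame, path) -> None:
    expr_values.to_csv(path, sep="\t")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json_report(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def write_imzml(dataset, path) -> None:
    """Write an MsiDataset-like object as continuous-mode imzML (.imzML +
    binary .ibd companion)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as w:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            w.addSpectrum(dataset.mz, dataset.spectrum(i), (int(x) + 1, int(y) + 1))


class ImzmlCollection:
    """Spectrum-access adapter over an imzML file, presenting the same
    ``mz`` / ``n_pixels`` / ``spectrum(i)`` surface as MsiDataset."""

    def __init__(self, path):
        from pyimzml.ImzMLParser import ImzMLParser

        self._parser = ImzMLParser(str(path))
        self.coords = np.array([(x - 1, y - 1) for x, y, _ in self._parser.coordinates])
        self.mz = np.asarray(self._parser.getspectrum(0)[0], dtype=float)

    @property
    def n_pixels(self) -> int:
        return len(self._parser.coordinates)

    def spectrum(self, i: int) -> np.ndarray:
        return np.asarray(self._parser.getspectrum(i)[1], dtype=float)


def write_peak_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.columns = [f"{c:.6f}" if isinstance(c, float) else str(c) for c in out.columns]
    out.to_csv(path, index_label="pixel_id")


def read_peak_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="pixel_id")
    df.columns = df.columns.astype(float)
    return df


def write_annotations(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return _read_table(path)
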