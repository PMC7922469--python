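"""Delimited-text readers/writers and run configuration.

The interchange format is tab-separated text: spectra as a ppm column plus
one column per sample (header row = sample ids), with a metadata sidecar
(sample_id, country, region, region_class, replicate). Output files carry
``# key=value`` comment headers recording the run's seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SpectrumSet

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_table",
    "read_table",
    "load_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

_META_COLS = ["sample_id", "country", "region", "region_class", "replicate"]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_spectra(
    spectra: SpectrumSet,
    path,
    metadata_path=None,
    header_meta: dict | None = None,
) -> None:
    """Write a SpectrumSet as TSV (ppm + one column per sample) + sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        spectra.intensities.T, columns=spectra.sample_ids
    )
    df.insert(0, "ppm", spectra.ppm)
    with open(path, "w") as fh:
        fh.write(_header_lines(header_meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            fh.write(_header_lines(header_meta))
            spectra.metadata.to_csv(fh, sep="\t", index=False)


def read_spectra(path, metadata_path=None) -> SpectrumSet:
    """Read spectra written by :func:`write_spectra`.

    A descending ppm axis is accepted and reversed (logged); non-monotone
    axes and metadata/sample mismatches raise descriptive errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "ppm" not in df.columns:
        raise ValueError(f"{path}: first column must be 'ppm'")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values in spectra table")
    ppm = df["ppm"].values.astype(float)
    inten = df.drop(columns="ppm").values.T.astype(float)
    sample_ids = [c for c in df.columns if c != "ppm"]
    d = np.diff(ppm)
    if np.all(d < 0):
        logger.info("%s: descending ppm axis reversed to ascending", path)
        ppm = ppm[::-1]
        inten = inten[:, ::-1]
    elif not np.all(d > 0):
        raise ValueError(f"{path}: ppm axis is not monotone")
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", comment="#")
        missing = [c for c in _META_COLS if c not in meta.columns]
        if missing:
            raise ValueError(f"{metadata_path}: missing columns {missing}")
        meta = meta.set_index("sample_id", drop=False)
        absent = [s for s in sample_ids if s not in meta.index]
        if absent:
            raise ValueError(
                f"{metadata_path}: no metadata for sample(s) {absent}"
            )
        meta = meta.loc[sample_ids].reset_index(drop=True)
    else:
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "country": "",
                "region": "",
                "region_class": "",
                "replicate": 0,
            }
        )
    return SpectrumSet(ppm=ppm, intensities=inten, metadata=meta)


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None, index=False):
    """Write a report table as TSV with a comment header."""
    with open(path, "w") as fh:
        fh.write(_header_lines(header_meta))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
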