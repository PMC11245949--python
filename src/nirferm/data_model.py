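"""Core containers and delimited-text I/O for NIR fermentation datasets.

A dataset is a flat CSV table: leading metadata columns (``sample_id`` plus
optional ``variety``, ``time_h``, ``subsample``, ``replicate``) followed by
one column per wavelength, with the header row giving the wavelength axis in
nanometres.  Reference chemistry (pH or total soluble solids) lives in a
separate two-column table keyed by ``sample_id`` and is aligned to the
spectra through an explicit join.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "variety", "time_h", "subsample", "replicate")

#: Valid spectral acquisition modes.
MODES = ("reflectance", "absorbance")

#: Known response variables and their units.
RESPONSE_UNITS = {"pH": "pH units", "TSS": "degrees Brix"}


class DataModelError(ValueError):
    """Raised when a container invariant or file contract is violated."""


@dataclass
class SpectrumSet:
    """A sample x wavelength matrix with its wavelength axis and metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength axis in nm, one entry per column.
    values
        2-D array, one row per spectrum.  Reflectance values must lie in
        (0, 1]; absorbance is unconstrained (but finite).
    mode
        Either ``"reflectance"`` or ``"absorbance"``.
    sample_ids
        One identifier per row; need not be unique across replicates of
        different samples, but joins require uniqueness.
    metadata
        Optional per-sample frame (variety, time_h, subsample, replicate),
        index-aligned with the rows of ``values``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.mode not in MODES:
            raise DataModelError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.wavelengths.ndim != 1:
            raise DataModelError("wavelength axis must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataModelError("wavelengths must be strictly increasing")
        if self.values.shape[1] != self.wavelengths.size:
            raise DataModelError(
                f"value matrix has {self.values.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataModelError("one sample_id required per spectrum row")
        if not np.all(np.isfinite(self.values)):
            raise DataModelError("spectra contain missing or non-finite values")
        if self.mode == "reflectance":
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise DataModelError("reflectance values must lie in (0, 1]")
        if self.metadata is not None and len(self.metadata) != self.values.shape[0]:
            raise DataModelError("metadata row count does not match spectra")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, mode: str | None = None) -> "SpectrumSet":
        """Return a copy carrying new values (and optionally a new mode)."""
        return replace(self, values=values, mode=mode or self.mode)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the CSV dialect (metadata columns then wavelengths)."""
        frame = pd.DataFrame({"sample_id": self.sample_ids})
        if self.metadata is not None:
            for col in self.metadata.columns:
                frame[col] = np.asarray(self.metadata[col])
        spectra = pd.DataFrame(
            self.values, columns=[format(w, "g") for w in self.wavelengths]
        )
        return pd.concat([frame.reset_index(drop=True), spectra], axis=1)


@dataclass
class ReferenceTable:
    """Per-sample reference chemistry for a single response variable."""

    sample_ids: list[str]
    y: np.ndarray
    response_name: str
    units: str = field(default="")

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float)
        if not self.units:
            self.units = RESPONSE_UNITS.get(self.response_name, "")
        self.validate()

    def validate(self) -> None:
        if self.y.ndim != 1 or len(self.sample_ids) != self.y.size:
            raise DataModelError("reference table needs one y value per sample_id")
        if not np.all(np.isfinite(self.y)):
            raise DataModelError("reference values must be finite")
        if self.response_name == "pH" and (np.any(self.y <= 0) or np.any(self.y >= 14)):
            raise DataModelError("pH values must lie in (0, 14)")
        if self.response_name == "TSS" and np.any(self.y < 0):
            raise DataModelError("TSS values must be non-negative")


@dataclass
class JoinedDataset:
    """A SpectrumSet with a response vector aligned to its row order."""

    spectra: SpectrumSet
    y: np.ndarray
    response_name: str

    @property
    def X(self) -> np.ndarray:
        return self.spectra.values


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_spectra(path, mode: str) -> SpectrumSet:
    """Read a spectra CSV: metadata columns, then wavelength columns in nm.

    The wavelength header must parse as numbers and be strictly increasing;
    any non-numeric cell in the spectral block is an error.
    """
    table = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in table.columns:
        raise DataModelError("spectra file must contain a sample_id column")
    meta_cols = [c for c in METADATA_COLUMNS if c in table.columns]
    wl_cols = [c for c in table.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise DataModelError(f"non-numeric wavelength header: {exc}") from None
    values = table[wl_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataModelError("non-numeric cell in the spectral block")
    metadata = table[[c for c in meta_cols if c != "sample_id"]]
    return SpectrumSet(
        wavelengths=wavelengths,
        values=values,
        mode=mode,
        sample_ids=list(table["sample_id"]),
        metadata=metadata if len(metadata.columns) else None,
    )


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Write the flat CSV dialect; full float precision is preserved."""
    spectra.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_reference(path, response_name: str) -> ReferenceTable:
    """Read a two-column sample_id / value table for one response."""
    table = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in table.columns:
        raise DataModelError("reference file must contain a sample_id column")
    value_cols = [c for c in table.columns if c != "sample_id"]
    col = response_name if response_name in value_cols else value_cols[0]
    return ReferenceTable(
        sample_ids=list(table["sample_id"]),
        y=table[col].to_numpy(dtype=float),
        response_name=response_name,
    )


def write_reference(refs: ReferenceTable, path) -> None:
    pd.DataFrame({"sample_id": refs.sample_ids, refs.response_name: refs.y}).to_csv(
        path, index=False, float_format="%.17g"
    )


def join_dataset(spectra: SpectrumSet, refs: ReferenceTable) -> JoinedDataset:
    """Align reference values to spectra rows by sample_id.

    Row order of the spectra is preserved; the reference table may arrive in
    any order.  Duplicate or missing ids are hard errors that name the
    offending id.
    """
    seen: dict[str, int] = {}
    for i, sid in enumerate(refs.sample_ids):
        if sid in seen:
            raise DataModelError(f"duplicate sample_id in reference table: {sid!r}")
        seen[sid] = i
    missing = [sid for sid in spectra.sample_ids if sid not in seen]
    if missing:
        raise DataModelError(f"sample_id missing from reference table: {missing[0]!r}")
    y = refs.y[[seen[sid] for sid in spectra.sample_ids]]
    return JoinedDataset(spectra=spectra, y=y, response_name=refs.response_name)
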