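"""Reading, validating and constructing canopy light-interception datasets.

A dataset is a flat table of (genotype, LAI, fPARi) records. LAI is the leaf
area index (leaf area per unit ground area, dimensionless, positive) and fPARi
is the fraction of photosynthetically active radiation intercepted by the
canopy, a proportion strictly inside (0, 1): the beta likelihood is undefined
at the endpoints and the log-transformed model needs log(1 - fPARi).

Also provides the field-derivation helpers used to construct LAI and fPARi
from raw canopy measurements (lamina dimensions, stand density, PAR fluxes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    MeasurementError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Logical column names a canopy table must provide (possibly remapped).
REQUIRED_COLUMNS = ("genotype", "lai", "fpari")


@dataclass(frozen=True)
class CanopyObservation:
    """One (genotype, LAI, fPARi) record.

    Value-range invariants (lai > 0, 0 < fpari < 1) are enforced by
    :func:`validate_dataset` / :func:`read_canopy_table`, not the constructor,
    so that the ``clamp`` endpoint policy can repair out-of-range fPARi.
    """

    genotype: str
    lai: float
    fpari: float


@dataclass
class Dataset:
    """Ordered collection of observations plus a genotype index.

    ``genotype_index`` maps each genotype label to a contiguous integer
    ``1..J`` assigned in first-appearance order. The index must cover exactly
    the labels appearing in ``observations``; an explicit index with *no*
    observations is allowed as an escape hatch for prior-only sampling.
    """

    observations: list[CanopyObservation] = field(default_factory=list)
    genotype_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = {o.genotype for o in self.observations}
        if self.observations:
            if seen != set(self.genotype_index):
                raise ValidationError(
                    "genotype_index must cover exactly the labels present in "
                    f"observations; index={sorted(self.genotype_index)} "
                    f"observed={sorted(seen)}"
                )
        if self.genotype_index:
            ranks = sorted(self.genotype_index.values())
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValidationError(
                    f"genotype_index values must be contiguous 1..J, got {ranks}"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_observations(cls, observations: Sequence[CanopyObservation]) -> "Dataset":
        """Build a dataset, assigning genotype ranks in first-appearance order."""
        index: dict[str, int] = {}
        for obs in observations:
            if obs.genotype not in index:
                index[obs.genotype] = len(index) + 1
        return cls(observations=list(observations), genotype_index=index)

    @classmethod
    def from_arrays(
        cls,
        genotype: Sequence[str],
        lai: Sequence[float],
        fpari: Sequence[float],
    ) -> "Dataset":
        if not (len(genotype) == len(lai) == len(fpari)):
            raise ConfigurationError("genotype, lai and fpari must have equal length")
        obs = [
            CanopyObservation(str(g), float(a), float(f))
            for g, a, f in zip(genotype, lai, fpari)
        ]
        return cls.from_observations(obs)

    # -- accessors ---------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_index)

    @property
    def genotypes(self) -> list[str]:
        """Genotype labels ordered by their index rank."""
        return sorted(self.genotype_index, key=self.genotype_index.__getitem__)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (lai, fpari, genotype_code) arrays; codes are 0-based ranks."""
        lai = np.array([o.lai for o in self.observations], dtype=float)
        fpari = np.array([o.fpari for o in self.observations], dtype=float)
        codes = np.array(
            [self.genotype_index[o.genotype] - 1 for o in self.observations],
            dtype=int,
        )
        return lai, fpari, codes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": [o.genotype for o in self.observations],
                "lai": [o.lai for o in self.observations],
                "fpari": [o.fpari for o in self.observations],
            }
        )

    def counts(self) -> dict[str, int]:
        """Observation count per genotype label."""
        out = {g: 0 for g in self.genotype_index}
        for o in self.observations:
            out[o.genotype] += 1
        return out


def read_canopy_table(
    path, column_map: Mapping[str, str] | None = None
) -> Dataset:
    """Read a comma-separated canopy table into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row. The dialect is fixed:
        comma-separated, ``.`` decimal, UTF-8.
    column_map
        Optional mapping of logical names (``genotype``, ``lai``, ``fpari``)
        to the actual column headers in the file.

    Row order is preserved and genotype ranks follow first appearance.
    Values are validated under the strict (reject) endpoint policy; offending
    rows are reported by their 1-based data-row number.
    """
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=",", dtype=str, encoding="utf-8")
    columns = {}
    for logical in REQUIRED_COLUMNS:
        header = column_map.get(logical, logical)
        if header not in frame.columns:
            raise ConfigurationError(
                f"required column {header!r} (logical {logical!r}) not found; "
                f"available: {list(frame.columns)}"
            )
        columns[logical] = header
    if frame.empty:
        raise ValidationError("empty dataset: file contains a header but no rows")

    genotype = frame[columns["genotype"]].astype(str)
    numeric = {}
    for logical in ("lai", "fpari"):
        raw = frame[columns[logical]]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValidationError(
                f"non-numeric {logical} value {raw.iloc[bad[0]]!r} in row {row}"
            )
        numeric[logical] = values.to_numpy(dtype=float)

    dataset = Dataset.from_arrays(genotype, numeric["lai"], numeric["fpari"])
    return validate_dataset(dataset, endpoint_policy="reject")


def write_canopy_table(dataset: Dataset, path) -> None:
    """Write the fixed CSV dialect; floats use shortest round-trip repr."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("genotype,lai,fpari\n")
        for o in dataset.observations:
            handle.write(f"{o.genotype},{o.lai!r},{o.fpari!r}\n")


def validate_dataset(
    dataset: Dataset,
    endpoint_policy: str = "reject",
    epsilon: float = 1e-6,
) -> Dataset:
    """Enforce value invariants: lai > 0 and fpari strictly inside (0, 1).

    Under ``reject`` any violation raises, listing offending 1-based rows.
    Under ``clamp`` out-of-range fpari is moved into ``[epsilon, 1-epsilon]``
    (a warning logs the count); lai <= 0 is always an error — clamping is an
    endpoint repair for the proportion only.
    """
    if endpoint_policy not in ("reject", "clamp"):
        raise ConfigurationError(
            f"endpoint_policy must be 'reject' or 'clamp', got {endpoint_policy!r}"
        )
    if endpoint_policy == "clamp" and not (0 < epsilon < 0.5):
        raise ConfigurationError(f"epsilon must be in (0, 0.5), got {epsilon}")

    bad_lai = [
        i + 1
        for i, o in enumerate(dataset.observations)
        if not (math.isfinite(o.lai) and o.lai > 0)
    ]
    if bad_lai:
        raise ValidationError(f"lai must be > 0; offending rows: {bad_lai}")

    bad_fpari = [
        i + 1
        for i, o in enumerate(dataset.observations)
        if not (math.isfinite(o.fpari) and 0 < o.fpari < 1)
    ]
    if endpoint_policy == "reject":
        if bad_fpari:
            raise ValidationError(
                f"fpari must lie strictly in (0, 1); offending rows: {bad_fpari}"
            )
        return dataset

    if not bad_fpari:
        return dataset
    clamped = []
    for i, o in enumerate(dataset.observations):
        if i + 1 in bad_fpari:
            if not math.isfinite(o.fpari):
                raise ValidationError(f"fpari is non-finite in row {i + 1}")
            new = min(max(o.fpari, epsilon), 1.0 - epsilon)
            clamped.append(CanopyObservation(o.genotype, o.lai, new))
        else:
            clamped.append(o)
    logger.warning(
        "clamped %d fpari value(s) into [%g, %g]", len(bad_fpari), epsilon, 1 - epsilon
    )
    return Dataset(observations=clamped, genotype_index=dict(dataset.genotype_index))


# -- field-derivation formulas -------------------------------------------


def leaf_area(length_cm: float, width_cm: float, alpha: float = 0.75) -> float:
    """Individual leaf lamina area (cm^2) from length, maximum width and a
    shape factor: ``alpha * L * W``."""
    if not (length_cm > 0 and width_cm > 0):
        raise DomainError("length_cm and width_cm must be positive")
    if not alpha > 0:
        raise DomainError("alpha must be positive")
    return alpha * length_cm * width_cm


def fpari_from_par(par_top: float, par_bottom: float) -> float:
    """Fraction of intercepted PAR: ``1 - par_bottom / par_top``."""
    if not par_top > 0:
        raise DomainError("par_top must be positive")
    if par_bottom < 0:
        raise DomainError("par_bottom must be non-negative")
    if par_bottom > par_top:
        raise MeasurementError(
            f"below-canopy PAR ({par_bottom}) exceeds incident PAR ({par_top})"
        )
    return 1.0 - par_bottom / par_top


def lai_from_plants(mean_leaf_area_per_plant: float, stand_density: float) -> float:
    """LAI from mean leaf area per plant (m^2) and stand density (plants/m^2)."""
    if not (mean_leaf_area_per_plant > 0 and stand_density > 0):
        raise DomainError("leaf area per plant and stand density must be positive")
    return mean_leaf_area_per_plant * stand_density
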