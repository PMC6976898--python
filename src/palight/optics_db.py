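"""Optical-property database for the simulated tissue and phantom materials.

The bundled table lists, per material and wavelength, the absorption
coefficient ``mu_a`` (1/mm), scattering coefficient ``mu_s`` (1/mm),
scattering anisotropy ``g`` (mean cosine of the single-scattering deflection
angle) and refractive index ``n``.  Soft-tissue entries (skin, fatty,
fibrous) all carry ``g = 0.9`` and ``n = 1.4``; the phantom materials (milk
coupling layer, gelatin bulk) are defined at 1064 nm only.

Intermediate soft-tissue compositions are modelled as a linear combination of
the purely fatty and purely fibrous endpoints: a mixture with fatty fraction
``f`` has ``mu_a = f * mu_a_fatty + (1 - f) * mu_a_fibrous`` and likewise for
``mu_s``.  Mixture values are always computed from the endpoint rows, never
tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd

__all__ = [
    "OpticalProperties",
    "TissueSpec",
    "UnknownTissueError",
    "get_properties",
    "load_table",
    "mix_properties",
]

WAVELENGTHS_NM = (700, 800, 900, 1064)

TissueKind = Literal["skin", "fatty", "fibrous", "mixed", "milk", "gelatin"]


class UnknownTissueError(KeyError):
    """Raised when a (tissue, wavelength) pair is not in the database."""


@dataclass(frozen=True)
class OpticalProperties:
    """Per-voxel-class optical quadruple (mu_a, mu_s, g, n).

    mu_a and mu_s are in 1/mm; g and n are dimensionless.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must be in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (1/mm)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class TissueSpec:
    """A material request: named tissue, or a fatty/fibrous mixture.

    ``fatty_fraction`` is required for (and only meaningful for)
    ``kind="mixed"``.
    """

    kind: TissueKind
    wavelength: int
    fatty_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "mixed":
            if self.fatty_fraction is None:
                raise ValueError("mixed tissue requires fatty_fraction")
            if not 0.0 <= self.fatty_fraction <= 1.0:
                raise ValueError(
                    f"fatty_fraction must be in [0, 1], got {self.fatty_fraction}"
                )
        elif self.fatty_fraction is not None:
            raise ValueError(f"fatty_fraction is only valid for mixed, not {self.kind}")

    @property
    def label(self) -> str:
        if self.kind == "mixed":
            return f"mixed{self.fatty_fraction:.0%}fatty@{self.wavelength}"
        return f"{self.kind}@{self.wavelength}"


def load_table() -> pd.DataFrame:
    """Load the bundled property table as a DataFrame."""
    with resources.files("palight.data").joinpath("optical_properties.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


_TABLE: dict[tuple[str, int], OpticalProperties] | None = None


def _table() -> dict[tuple[str, int], OpticalProperties]:
    global _TABLE
    if _TABLE is None:
        df = load_table()
        _TABLE = {
            (row.tissue, int(row.wavelength_nm)): OpticalProperties(
                mu_a=float(row.mu_a_per_mm),
                mu_s=float(row.mu_s_per_mm),
                g=float(row.g),
                n=float(row.n),
            )
            for row in df.itertuples()
        }
    return _TABLE


def get_properties(spec: TissueSpec) -> OpticalProperties:
    """Look up (or, for mixtures, compute) the optical quadruple for ``spec``.

    Raises
    ------
    UnknownTissueError
        If the tissue/wavelength pair has no database entry.
    """
    if spec.kind == "mixed":
        assert spec.fatty_fraction is not None
        return mix_properties(spec.fatty_fraction, spec.wavelength)
    try:
        return _table()[(spec.kind, spec.wavelength)]
    except KeyError:
        raise UnknownTissueError(
            f"no optical properties for tissue {spec.kind!r} at "
            f"{spec.wavelength} nm"
        ) from None


def mix_properties(fatty_fraction: float, wavelength: int) -> OpticalProperties:
    """Linear fatty/fibrous mixture at the given wavelength.

    mu_a and mu_s are the convex combination
    ``f * fatty + (1 - f) * fibrous`` of the endpoint rows; g and n are the
    common soft-tissue values (0.9, 1.4).
    """
    if not 0.0 <= fatty_fraction <= 1.0:
        raise ValueError(f"fatty_fraction must be in [0, 1], got {fatty_fraction}")
    fat = get_properties(TissueSpec("fatty", wavelength))
    fib = get_properties(TissueSpec("fibrous", wavelength))
    f = fatty_fraction
    return OpticalProperties(
        mu_a=f * fat.mu_a + (1.0 - f) * fib.mu_a,
        mu_s=f * fat.mu_s + (1.0 - f) * fib.mu_s,
        g=fat.g,
        n=fat.n,
    )
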