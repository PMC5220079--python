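"""Spectral reflectance index (SRI) definitions, registry and evaluation.

An SRI is an arithmetic combination of reflectances at specific bands,
designed to track a plant trait while staying relatively immune to
illumination changes (NDVI for greenness/biomass, PRI for xanthophyll
activity, WI for canopy water status, ...).  Definitions are written as
plain arithmetic expressions over band tokens::

    NDVI:  (R800 - R670) / (R800 + R670)

with operators ``+ - * / **`` and numeric constants.  Band tokens are
``R`` followed by the wavelength in nm (decimals as ``R531.5``).  At
evaluation time each band is matched to the nearest wavelength of the
spectrum's grid within a tolerance (default 3 nm, ties to the lower
wavelength); an unmatched or missing band, or a division by zero, makes the
index value missing rather than raising.

The built-in registry ships a curated, citation-tagged subset of the
published index literature plus template constructors for the two most
common families (normalized difference, simple ratio); user files with one
``name; citation; expression`` entry per line extend it.
"""

from __future__ import annotations

import ast
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np

from .errors import ExpressionError, LookupError, RegistrationError
from .spectral_io import ScanAverages

_BAND_TOKEN = re.compile(r"R(\d+(?:\.\d+)?)")


def _band_name(nm: float) -> str:
    """Internal identifier for a band token (R531.5 -> R531_5)."""
    s = f"{nm:g}".replace(".", "_")
    return f"R{s}"


def _extract_bands(expression: str) -> tuple[float, ...]:
    return tuple(sorted({float(m.group(1)) for m in _BAND_TOKEN.finditer(expression)}))


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


def _compile_expression(expression: str) -> Callable[[dict[str, float]], float]:
    """Compile an index expression to a callable over band values.

    Only arithmetic (+ - * / ** and unary sign), numeric constants and band
    tokens are admitted; anything else is a parse error.
    """
    src = _BAND_TOKEN.sub(lambda m: _band_name(float(m.group(1))), expression)
    try:
        tree = ast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expression!r}: {exc}") from None

    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Constant, ast.Name, ast.Load)):
            if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
                raise ExpressionError(f"non-numeric constant in {expression!r}")
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            continue
        if isinstance(node, _ALLOWED_BINOPS + _ALLOWED_UNARY):
            continue
        raise ExpressionError(
            f"disallowed construct {type(node).__name__} in {expression!r}"
        )

    code = compile(tree, "<sri>", "eval")

    def evaluate(env: dict[str, float]) -> float:
        return float(eval(code, {"__builtins__": {}}, env))  # noqa: S307 - whitelisted AST

    return evaluate


@dataclass(frozen=True)
class SRIDefinition:
    """A named index: expression over band reflectances + citation tag."""

    name: str
    citation: str
    expression: str
    bands: tuple[float, ...] = ()
    _eval: Callable[[dict[str, float]], float] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        used = _extract_bands(self.expression)
        if not self.bands:
            object.__setattr__(self, "bands", used)
        else:
            declared = set(float(b) for b in self.bands)
            missing = [b for b in used if b not in declared]
            if missing:
                raise ExpressionError(
                    f"{self.name}: bands {missing} used in expression but not "
                    "declared"
                )
            object.__setattr__(self, "bands", tuple(sorted(declared)))
        object.__setattr__(self, "_eval", _compile_expression(self.expression))

    def evaluate(self, band_values: dict[float, float]) -> float:
        """Value of the index given reflectance per required band.

        Missing (NaN) band values and zero divisions give NaN.
        """
        env = {}
        for b in _extract_bands(self.expression):
            v = band_values.get(b, np.nan)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return float("nan")
            env[_band_name(b)] = float(v)
        try:
            return self._eval(env)
        except ZeroDivisionError:
            return float("nan")
        except OverflowError:
            return float("inf")


@dataclass(frozen=True)
class BandMatchPolicy:
    """Nearest-grid-wavelength band matching within ``tolerance_nm``."""

    tolerance_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.tolerance_nm < 0:
            raise ValueError("tolerance_nm must be >= 0")


def match_band(
    wavelengths: np.ndarray, band_nm: float, policy: BandMatchPolicy
) -> int | None:
    """Index of the grid wavelength nearest to ``band_nm`` within tolerance.

    Exact distance ties resolve to the lower wavelength.  None if no grid
    wavelength lies within the tolerance.
    """
    wl = np.asarray(wavelengths, dtype=float)
    dist = np.abs(wl - band_nm)
    j = int(np.argmin(dist))  # argmin takes the first (= lower wl) on ties
    if dist[j] <= policy.tolerance_nm:
        return j
    return None


class SRIRegistry:
    """Name-keyed collection of SRI definitions."""

    def __init__(self) -> None:
        self._defs: dict[str, SRIDefinition] = {}

    def register(self, definition: SRIDefinition) -> SRIDefinition:
        if definition.name in self._defs:
            raise RegistrationError(f"index {definition.name!r} already registered")
        self._defs[definition.name] = definition
        return definition

    def get(self, name: str) -> SRIDefinition:
        try:
            return self._defs[name]
        except KeyError:
            raise LookupError(f"unknown index {name!r}") from None

    def names(self) -> list[str]:
        return list(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __iter__(self) -> Iterator[SRIDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def load_definitions(self, path: str | Path) -> list[SRIDefinition]:
        """Extend the registry from a ``name; citation; expression`` file.

        Blank lines and ``#`` comments are ignored.
        """
        added = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(";")]
            if len(parts) != 3:
                raise ExpressionError(
                    f"{path}:{lineno}: expected 'name; citation; expression'"
                )
            added.append(
                self.register(
                    SRIDefinition(name=parts[0], citation=parts[1], expression=parts[2])
                )
            )
        return added


def normalized_difference(name: str, band_a: float, band_b: float,
                          citation: str = "template") -> SRIDefinition:
    """(Ra - Rb) / (Ra + Rb) — bounded in [-1, 1] for positive reflectances."""
    return SRIDefinition(
        name=name, citation=citation,
        expression=f"(R{band_a:g} - R{band_b:g}) / (R{band_a:g} + R{band_b:g})",
    )


def simple_ratio(name: str, band_a: float, band_b: float,
                 citation: str = "template") -> SRIDefinition:
    """Ra / Rb."""
    return SRIDefinition(
        name=name, citation=citation, expression=f"R{band_a:g} / R{band_b:g}",
    )


# ---------------------------------------------------------------------------
# curated built-in registry
# ---------------------------------------------------------------------------

_BUILTINS: list[tuple[str, str, str]] = [
    ("SR", "Jordan 1969", "R800 / R670"),
    ("NDVI", "Rouse et al. 1974", "(R800 - R670) / (R800 + R670)"),
    ("DVI", "Tucker 1979", "R800 - R670"),
    ("GNDVI", "Gitelson et al. 1996", "(R800 - R550) / (R800 + R550)"),
    ("RDVI", "Roujean & Breon 1995", "(R800 - R670) / (R800 + R670) ** 0.5"),
    ("MSR", "Chen 1996", "(R800 / R670 - 1) / ((R800 / R670) ** 0.5 + 1)"),
    ("SAVI", "Huete 1988", "1.5 * (R800 - R670) / (R800 + R670 + 0.5)"),
    ("OSAVI", "Rondeaux et al. 1996", "1.16 * (R800 - R670) / (R800 + R670 + 0.16)"),
    ("EVI", "Huete et al. 2002",
     "2.5 * (R800 - R670) / (R800 + 6 * R670 - 7.5 * R475 + 1)"),
    ("PRI", "Gamon et al. 1992", "(R531 - R570) / (R531 + R570)"),
    ("WI", "Penuelas et al. 1997", "R900 / R970"),
    ("WBI", "Penuelas et al. 1993", "R970 / R900"),
    ("NDWI", "Gao 1996", "(R860 - R1240) / (R860 + R1240)"),
    ("SRWI", "Zarco-Tejada et al. 2003", "R858 / R1240"),
    ("MSI", "Hunt & Rock 1989", "R1600 / R820"),
    ("NDII", "Hardisky et al. 1983", "(R820 - R1600) / (R820 + R1600)"),
    ("SIPI", "Penuelas et al. 1995", "(R800 - R445) / (R800 - R680)"),
    ("TVI", "Broge & Leblanc 2000",
     "0.5 * (120 * (R750 - R550) - 200 * (R670 - R550))"),
    ("MTVI1", "Haboudane et al. 2004",
     "1.2 * (1.2 * (R800 - R550) - 2.5 * (R670 - R550))"),
    ("MCARI", "Daughtry et al. 2000",
     "((R700 - R670) - 0.2 * (R700 - R550)) * (R700 / R670)"),
    ("TCARI", "Haboudane et al. 2002",
     "3 * ((R700 - R670) - 0.2 * (R700 - R550) * (R700 / R670))"),
    ("CRI", "Gitelson et al. 2002", "1 / R510 - 1 / R550"),
    ("ARI", "Gitelson et al. 2001", "1 / R550 - 1 / R700"),
    ("MTCI", "Dash & Curran 2004", "(R754 - R709) / (R709 - R681)"),
    ("NDRE", "Barnes et al. 2000", "(R790 - R720) / (R790 + R720)"),
    ("VARI", "Gitelson et al. 2002", "(R550 - R670) / (R550 + R670 - R475)"),
    ("NPCI", "Penuelas et al. 1994", "(R680 - R430) / (R680 + R430)"),
    ("NPQI", "Barnes et al. 1992", "(R415 - R435) / (R415 + R435)"),
    ("PSRI", "Merzlyak et al. 1999", "(R680 - R500) / R750"),
    ("CTR1", "Carter 1994", "R695 / R420"),
    ("CTR2", "Carter 1994", "R695 / R760"),
    ("VOG1", "Vogelmann et al. 1993", "R740 / R720"),
    ("VOG2", "Vogelmann et al. 1993", "(R734 - R747) / (R715 + R726)"),
    ("GM1", "Gitelson & Merzlyak 1997", "R750 / R550"),
    ("GM2", "Gitelson & Merzlyak 1997", "R750 / R700"),
    ("ZM", "Zarco-Tejada et al. 2001", "R750 / R710"),
    ("RGR", "Gamon & Surfus 1999", "R690 / R550"),
    ("GI", "Zarco-Tejada et al. 2005", "R554 / R677"),
    ("PSSRa", "Blackburn 1998", "R800 / R680"),
    ("PSSRb", "Blackburn 1998", "R800 / R635"),
    ("PSNDa", "Blackburn 1998", "(R800 - R680) / (R800 + R680)"),
    ("SR705", "Sims & Gamon 2002", "R750 / R705"),
    ("ND705", "Sims & Gamon 2002", "(R750 - R705) / (R750 + R705)"),
    ("mSR705", "Sims & Gamon 2002", "(R750 - R445) / (R705 - R445)"),
    ("mND705", "Sims & Gamon 2002", "(R750 - R705) / (R750 + R705 - 2 * R445)"),
    ("Datt", "Datt 1999", "(R850 - R710) / (R850 - R680)"),
    ("DLAI", "Le Maire et al. 2008", "R1725 - R970"),
]


def builtin_registry() -> SRIRegistry:
    """Registry preloaded with the curated literature indices."""
    registry = SRIRegistry()
    for name, citation, expression in _BUILTINS:
        registry.register(
            SRIDefinition(name=name, citation=citation, expression=expression)
        )
    return registry


# ---------------------------------------------------------------------------
# evaluation on spectra
# ---------------------------------------------------------------------------


def compute_sri(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    definition: SRIDefinition,
    policy: BandMatchPolicy = BandMatchPolicy(),
) -> float:
    """Index value on one (scan-averaged) spectrum; NaN when undefined."""
    band_values: dict[float, float] = {}
    for band in definition.bands:
        j = match_band(wavelengths, band, policy)
        band_values[band] = np.nan if j is None else float(spectrum[j])
    return definition.evaluate(band_values)


def compute_sri_matrix(
    averages: ScanAverages,
    definitions: list[SRIDefinition],
    policy: BandMatchPolicy = BandMatchPolicy(),
) -> "np.ndarray":
    """Values for several indices over all scans; shape (n_scans, n_defs)."""
    out = np.full((averages.n_scans, len(definitions)), np.nan)
    for j, definition in enumerate(definitions):
        cols = {b: match_band(averages.wavelengths, b, policy) for b in definition.bands}
        for i in range(averages.n_scans):
            band_values = {
                b: (np.nan if c is None else float(averages.values[i, c]))
                for b, c in cols.items()
            }
            out[i, j] = definition.evaluate(band_values)
    return out
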