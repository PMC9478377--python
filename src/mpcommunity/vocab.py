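"""Closed category vocabularies for soil microplastic surveys.

A microplastic (MP) particle is characterised by four categorical
attributes — size class, shape, colour and polymer type — plus the sample
it came from and that sample's region and depth layer.  The vocabularies
below are the canonical levels used throughout the package; free-text
input is mapped onto them by :func:`canonicalize` (case-insensitive,
whitespace-collapsed, dash-normalised, with a synonym map for common
alternative spellings such as "polyethylene" for PE or "nylon" for PA).

MPs are particles below 5 mm; size values outside the four classes are
rejected rather than silently binned.
"""

from __future__ import annotations

import re

from .errors import VocabularyError

REGIONS = ("SD", "HE", "TJ", "HN", "DB")
DEPTH_LAYERS = ("0-20 cm", "20-40 cm")
SIZE_CLASSES = ("<0.5 mm", "0.5-1 mm", "1-2 mm", "2-5 mm")
SHAPES = ("fiber", "pellet", "fragment", "foam", "film")
COLORS = ("white", "black", "transparent", "blue", "other")
POLYMERS = ("Rayon", "PE", "PP", "PP+PE", "PET", "Polyester", "Acrylic", "PS", "PA")

#: attribute family name -> canonical levels, in canonical order
FAMILIES: dict[str, tuple[str, ...]] = {
    "region": REGIONS,
    "depth_layer": DEPTH_LAYERS,
    "size_class": SIZE_CLASSES,
    "shape": SHAPES,
    "color": COLORS,
    "polymer": POLYMERS,
}

# normalised spelling -> canonical level, per family; the identity map for
# every canonical level is added automatically.
_SYNONYMS: dict[str, dict[str, str]] = {
    "region": {
        "shandong": "SD",
        "henan": "HE",
        "tianjin": "TJ",
        "tianjing": "TJ",
        "hunan": "HN",
        "heilongjiang": "DB",
        "dongbei": "DB",
    },
    "depth_layer": {
        "topsoil": "0-20 cm",
        "subsoil": "20-40 cm",
        "0-20": "0-20 cm",
        "20-40": "20-40 cm",
        "0-20cm": "0-20 cm",
        "20-40cm": "20-40 cm",
        "0-20 cm": "0-20 cm",
        "20-40 cm": "20-40 cm",
    },
    "size_class": {
        "<0.5": "<0.5 mm",
        "<0.5mm": "<0.5 mm",
        "< 0.5 mm": "<0.5 mm",
        "0.5-1": "0.5-1 mm",
        "0.5-1mm": "0.5-1 mm",
        "1-2": "1-2 mm",
        "1-2mm": "1-2 mm",
        "2-5": "2-5 mm",
        "2-5mm": "2-5 mm",
    },
    "shape": {"fibre": "fiber"},
    "color": {"colourless": "transparent", "clear": "transparent", "others": "other"},
    "polymer": {
        "polyethylene": "PE",
        "polypropylene": "PP",
        "pp + pe": "PP+PE",
        "pe+pp": "PP+PE",
        "polyethylene terephthalate": "PET",
        "polystyrene": "PS",
        "nylon": "PA",
        "pa (nylon)": "PA",
        "polyamide": "PA",
    },
}

_DASHES = re.compile(r"[‐-―−]")  # unicode hyphens/dashes/minus
_WS = re.compile(r"\s+")


def _normalize(value: str) -> str:
    """Lower-case, collapse whitespace, unify dashes, strip space around '-'."""
    v = _DASHES.sub("-", str(value)).strip().lower()
    v = _WS.sub(" ", v)
    v = re.sub(r"\s*-\s*", "-", v)
    return v


def _lookup_tables() -> dict[str, dict[str, str]]:
    tables: dict[str, dict[str, str]] = {}
    for family, levels in FAMILIES.items():
        table = {_normalize(level): level for level in levels}
        table.update(
            {_normalize(k): v for k, v in _SYNONYMS.get(family, {}).items()}
        )
        tables[family] = table
    return tables


_LOOKUP = _lookup_tables()


def canonicalize(value: str, family: str, policy: str = "strict") -> str:
    """Map a raw categorical value onto its canonical vocabulary level.

    Parameters
    ----------
    value :
        Raw string as found in an input table.
    family :
        One of ``region, depth_layer, size_class, shape, color, polymer``.
    policy :
        ``"strict"`` raises :class:`VocabularyError` for unknown values;
        ``"permissive"`` coerces them to the literal level ``"other"``.

    Canonicalization is idempotent: canonical levels map to themselves.
    """
    if family not in FAMILIES:
        raise VocabularyError(f"unknown attribute family {family!r}")
    hit = _LOOKUP[family].get(_normalize(value))
    if hit is not None:
        return hit
    if policy == "strict":
        raise VocabularyError(
            f"value {value!r} is not in the closed {family} vocabulary "
            f"{list(FAMILIES[family])}"
        )
    if policy == "permissive":
        return "other"
    raise VocabularyError(f"unknown vocabulary policy {policy!r}")


def is_canonical(value: str, family: str) -> bool:
    return value in FAMILIES.get(family, ())
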