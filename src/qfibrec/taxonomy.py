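"""Canonical collagen feature taxonomy: 100 morphological + 76 ratio features.

The quantification grid describes collagen in four regions of liver tissue --
the *overlap* region (everything) and three architectural compartments:
*portal* (portal-tract expansion), *septal* (bridging fibrosis) and
*fibrillar* (fine pericellular/perisinusoidal collagen).  Within each
compartment collagen is further split into two patterns: *aggregated* (large
patches) and *distributed* (fine fibers).

Feature names follow the convention ``measurement + region letter + pattern
letter``: region letters are ``P``/``S``/``F`` (no letter = overlap region),
pattern letters are ``A``/``D`` (no letter = both patterns pooled).  So
``NoThickStrFA`` counts thick strings among aggregated fibrillar collagen and
``StrAreaPA`` is the summed string area of aggregated portal collagen.

The grid totals exactly 100 morphological features:

* overlap cell: ``SHG`` (collagen area percent) + 9 string summaries;
* each of portal/septal/fibrillar: 3 area-percent features (total, ``AGG``,
  ``DIS``) + 9 string summaries for each of the three pattern cells
  (pooled/aggregated/distributed), i.e. 30 per compartment.

The 76 ratio ("relativistic") features are, for each of the ten
(region, pattern) cells, seven canonical count/shape ratios, plus the six
area ratios ``{Portal,Septal,Fibrillar}{AGG,DIS}/{region total}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = ("portal", "septal", "fibrillar")
REGION_LETTER = {"overlap": "", "portal": "P", "septal": "S", "fibrillar": "F"}
REGION_WORD = {"portal": "Portal", "septal": "Septal", "fibrillar": "Fibrillar"}
PATTERNS = ("all", "aggregated", "distributed")
PATTERN_LETTER = {"all": "", "aggregated": "A", "distributed": "D"}

#: per-cell string summaries, in canonical order
STRING_SUMMARIES = (
    "NoStr",
    "NoShortStr",
    "NoLongStr",
    "NoThinStr",
    "NoThickStr",
    "StrArea",
    "StrLength",
    "StrWidth",
    "StrOrientation",
)

#: the ten (region, pattern) cells, in canonical order
CELLS = (("overlap", "all"),) + tuple(
    (r, p) for r in REGIONS for p in PATTERNS
)

#: numerator/denominator measurement pairs forming the per-cell ratios
RATIO_PAIRS = (
    ("NoShortStr", "NoLongStr"),
    ("NoThinStr", "NoThickStr"),
    ("StrLength", "StrWidth"),
    ("NoShortStr", "NoStr"),
    ("NoLongStr", "NoStr"),
    ("NoThinStr", "NoStr"),
    ("NoThickStr", "NoStr"),
)

POOLS = ("combined", "overlap", "portal", "septal", "fibrillar")


def cell_suffix(region: str, pattern: str) -> str:
    """Name suffix for a (region, pattern) cell, e.g. ``('septal','aggregated') -> 'SA'``."""
    return REGION_LETTER[region] + PATTERN_LETTER[pattern]


def _build_morphological() -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    region_of: dict[str, str] = {}

    def add(name: str, region: str) -> None:
        names.append(name)
        region_of[name] = region

    add("SHG", "overlap")
    for s in STRING_SUMMARIES:
        add(s, "overlap")
    for region in REGIONS:
        word = REGION_WORD[region]
        add(word, region)
        add(word + "AGG", region)
        add(word + "DIS", region)
        for pattern in PATTERNS:
            sfx = cell_suffix(region, pattern)
            for s in STRING_SUMMARIES:
                add(s + sfx, region)
    return names, region_of


def _build_relativistic() -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    region_of: dict[str, str] = {}
    for region, pattern in CELLS:
        sfx = cell_suffix(region, pattern)
        for num, den in RATIO_PAIRS:
            name = f"{num}{sfx}/{den}{sfx}"
            names.append(name)
            region_of[name] = region
    for region in REGIONS:
        word = REGION_WORD[region]
        for pat in ("AGG", "DIS"):
            name = f"{word}{pat}/{word}"
            names.append(name)
            region_of[name] = region
    return names, region_of


@dataclass(frozen=True)
class FeatureTaxonomy:
    """Ordered feature name lists plus region bookkeeping.

    ``relativistic`` names are always of the form ``"<num>/<den>"`` with both
    sides present among the morphological names.
    """

    morphological: tuple[str, ...]
    relativistic: tuple[str, ...]
    _region_of: dict[str, str] = field(repr=False, default_factory=dict)

    @classmethod
    def default(cls) -> "FeatureTaxonomy":
        morph, morph_regions = _build_morphological()
        rel, rel_regions = _build_relativistic()
        region_of = {**morph_regions, **rel_regions}
        return cls(tuple(morph), tuple(rel), region_of)

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.morphological + self.relativistic

    def __len__(self) -> int:
        return len(self.morphological) + len(self.relativistic)

    def __contains__(self, name: str) -> bool:
        return name in self._region_of

    def region_of(self, name: str) -> str:
        """Region ('overlap'/'portal'/'septal'/'fibrillar') a feature describes."""
        return self._region_of[name]

    def pool(self, pool: str) -> tuple[str, ...]:
        """Candidate feature names for a selection pool.

        ``combined`` is all 176 features; a region pool restricts to features
        describing that region (including its ratio features).
        """
        if pool == "combined":
            return self.all_names
        if pool not in REGION_LETTER:
            raise ValueError(f"unknown pool {pool!r}; expected one of {POOLS}")
        return tuple(n for n in self.all_names if self._region_of[n] == pool)

    def ratio_parts(self, name: str) -> tuple[str, str]:
        """Split a relativistic name into (numerator, denominator) morphological names."""
        num, den = name.split("/")
        return num, den


DEFAULT_TAXONOMY = FeatureTaxonomy.default()
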