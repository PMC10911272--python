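"""Site catalog for human rRNA 2'-O-methylation positions.

Sites live on the mature rRNA species (18S, 28S, 5.8S) in 1-based
coordinates.  The field convention labels each site by subunit prefix
(``SSU`` for 18S, ``LSU`` for 28S), the modified nucleotide, and the
position, e.g. ``LSU-G3723`` (guided by SNORD87).  5.8S sites keep their
species name as prefix (``5.8S-G75``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MethylSite",
    "SiteCatalog",
    "CatalogFormatError",
    "CatalogValidationError",
    "SiteLabelError",
    "DEFAULT_REFERENCE_LENGTHS",
    "load_site_catalog",
    "write_site_catalog",
    "default_catalog",
    "parse_site_label",
    "site_distance",
]

SUBUNITS = ("18S", "28S", "5.8S")
NUCLEOTIDES = ("A", "C", "G", "U")

#: subunit-prefix convention used in site labels
_PREFIX_TO_SUBUNIT = {"SSU": "18S", "LSU": "28S", "5.8S": "5.8S"}
_SUBUNIT_TO_PREFIX = {"18S": "SSU", "28S": "LSU", "5.8S": "5.8S"}

#: mature human rRNA lengths (nt) used by the bundled catalog
DEFAULT_REFERENCE_LENGTHS: Mapping[str, int] = {"18S": 1869, "28S": 5070, "5.8S": 157}

_LABEL_RE = re.compile(r"^(SSU|LSU|5\.8S)-([ACGU])([0-9]+)$")
_BARE_RE = re.compile(r"^([ACGU])([0-9]+)$")

_CATALOG_COLUMNS = ("subunit", "position", "nucleotide", "label", "guides")


class CatalogFormatError(ValueError):
    """Raised when a catalog file does not match the expected TSV schema."""


class CatalogValidationError(ValueError):
    """Raised when catalog contents violate an invariant (duplicates, range)."""


class SiteLabelError(ValueError):
    """Raised when a site label cannot be parsed."""


def parse_site_label(label: str, subunit: str | None = None) -> tuple[str, str, int]:
    """Parse a site label into ``(subunit, nucleotide, position)``.

    Accepts the prefixed form (``"LSU-G3723"`` -> ``("28S", "G", 3723)``) or a
    bare ``"G3723"`` when ``subunit`` supplies the context.
    """
    m = _LABEL_RE.match(label)
    if m:
        prefix, nt, pos = m.groups()
        return _PREFIX_TO_SUBUNIT[prefix], nt, int(pos)
    m = _BARE_RE.match(label)
    if m and subunit is not None:
        if subunit not in SUBUNITS:
            raise SiteLabelError(f"unknown subunit context {subunit!r} for label {label!r}")
        nt, pos = m.groups()
        return subunit, nt, int(pos)
    raise SiteLabelError(f"malformed site label: {label!r}")


def format_site_label(subunit: str, nucleotide: str, position: int) -> str:
    return f"{_SUBUNIT_TO_PREFIX[subunit]}-{nucleotide}{position}"


@dataclass(frozen=True)
class MethylSite:
    """One catalogued 2'-O-methylated ribose on a mature rRNA."""

    subunit: str
    position: int
    nucleotide: str
    label: str
    guide_snoRNAs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subunit not in SUBUNITS:
            raise CatalogValidationError(f"unknown subunit {self.subunit!r}")
        if self.nucleotide not in NUCLEOTIDES:
            raise CatalogValidationError(f"unknown nucleotide {self.nucleotide!r}")
        if self.position < 1:
            raise CatalogValidationError(f"position must be >= 1, got {self.position}")
        parsed = parse_site_label(self.label, subunit=self.subunit)
        if parsed != (self.subunit, self.nucleotide, self.position):
            raise CatalogValidationError(
                f"label {self.label!r} does not match fields "
                f"({self.subunit}, {self.nucleotide}, {self.position})"
            )


@dataclass(frozen=True)
class SiteCatalog:
    """Ordered collection of methylation sites plus reference lengths."""

    sites: tuple[MethylSite, ...]
    reference_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        dups = []
        for s in self.sites:
            key = (s.subunit, s.position)
            if key in seen:
                dups.append(f"{s.subunit}:{s.position}")
            seen[key] = s.label
        if dups:
            raise CatalogValidationError(
                "duplicate (subunit, position) entries: " + ", ".join(dups)
            )
        for s in self.sites:
            length = self.reference_lengths.get(s.subunit)
            if length is None:
                raise CatalogValidationError(
                    f"no reference length for subunit {s.subunit!r} (site {s.label})"
                )
            if s.position > length:
                raise CatalogValidationError(
                    f"site {s.label} position {s.position} exceeds "
                    f"{s.subunit} length {length}"
                )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[MethylSite]:
        return iter(self.sites)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    def get(self, label: str) -> MethylSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"site {label!r} not in catalog")

    def __contains__(self, label: str) -> bool:
        return any(s.label == label for s in self.sites)

    def sites_on(self, subunit: str) -> list[MethylSite]:
        return [s for s in self.sites if s.subunit == subunit]

    def guide_map(self) -> dict[str, list[str]]:
        """Map each guide snoRNA name to the labels of the sites it guides."""
        out: dict[str, list[str]] = {}
        for s in self.sites:
            for g in s.guide_snoRNAs:
                out.setdefault(g, []).append(s.label)
        return out


def _parse_guides(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(g.strip() for g in cell.split(",") if g.strip())


def load_site_catalog(
    path: str | Path,
    reference_lengths: Mapping[str, int] | None = None,
) -> SiteCatalog:
    """Load a catalog from a TSV with columns subunit/position/nucleotide/label/guides.

    Lines starting with ``#`` are comments.  File order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if reference_lengths is None:
        reference_lengths = DEFAULT_REFERENCE_LENGTHS
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise CatalogFormatError(f"{path}: empty catalog file (no header)")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _CATALOG_COLUMNS if c not in header]
    if missing:
        raise CatalogFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in _CATALOG_COLUMNS}
    sites = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        try:
            site = MethylSite(
                subunit=cells[idx["subunit"]],
                position=int(cells[idx["position"]]),
                nucleotide=cells[idx["nucleotide"]],
                label=cells[idx["label"]],
                guide_snoRNAs=_parse_guides(cells[idx["guides"]]),
            )
        except (ValueError, CatalogValidationError) as exc:
            raise CatalogFormatError(f"{path}:{lineno}: {exc}") from exc
        sites.append(site)
    return SiteCatalog(sites=tuple(sites), reference_lengths=dict(reference_lengths))


def write_site_catalog(catalog: SiteCatalog, path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(_CATALOG_COLUMNS)]
    for s in catalog.sites:
        rows.append(
            "\t".join(
                [s.subunit, str(s.position), s.nucleotide, s.label, ",".join(s.guide_snoRNAs)]
            )
        )
    path.write_text("\n".join(rows) + "\n")


def default_catalog() -> SiteCatalog:
    """The bundled 104-site human rRNA 2'-O-Me catalog."""
    with resources.as_file(
        resources.files("ribomethdiff.data").joinpath("sites_104.tsv")
    ) as p:
        return load_site_catalog(p, DEFAULT_REFERENCE_LENGTHS)


def site_distance(catalog: SiteCatalog, label_a: str, label_b: str) -> int:
    """Nucleotide distance |pos_a - pos_b| between two same-subunit sites."""
    a = catalog.get(label_a)
    b = catalog.get(label_b)
    if a.subunit != b.subunit:
        raise ValueError(
            f"sites on different subunits: {label_a} ({a.subunit}) vs {label_b} ({b.subunit})"
        )
    return abs(a.position - b.position)
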