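"""Protein domain architecture, binding-site registry and residue environment.

The annotation answers three questions about a residue position: which domain
it falls in, whether it is buried or surface-exposed (and between helices),
and how far it is from the nearest known ligand-binding site in sequence.

Domains are 1-based inclusive intervals; a domain may be discontinuous (e.g.
talin R7, which wraps around the inserted R8). The bundled talin-1 annotation
is frozen from structure-fragment boundaries and construct ranges; see
``docs/methods.md`` of the distribution for how gaps were closed.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import AnnotationError, PositionError

INTER_DOMAIN = "inter-domain"
DEFAULT_RSA_THRESHOLD = 0.20
DEFAULT_PROXIMITY_WINDOW = 10


@dataclass(frozen=True)
class DomainInterval:
    """A named domain made of one or more non-overlapping segments."""

    name: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for start, end in self.segments:
            if start > end or start < 1:
                raise AnnotationError(f"bad segment ({start},{end}) in domain {self.name}")
        spans = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise AnnotationError(f"overlapping segments in domain {self.name}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.segments)


@dataclass(frozen=True)
class BindingSite:
    """A ligand/partner site as a set of residue indices.

    ``host_domain`` is optional: sites spanning several domains (e.g. the
    C-terminal actin-binding site across R13 and DD) leave it unset and are
    then only checked against the sequence bounds.
    """

    name: str
    residues: frozenset[int]
    host_domain: str | None = None

    def __post_init__(self):
        if not self.residues:
            raise AnnotationError(f"binding site {self.name} has no residues")


@dataclass(frozen=True)
class ResidueEnvironment:
    """Structural context of one residue."""

    position: int
    location_class: str  # "buried" | "surface"
    between_helices: bool = False
    rsa: float | None = None


@dataclass
class ProteinAnnotation:
    """Indexed annotation supporting O(log n) point queries."""

    protein: str
    length: int
    domains: list[DomainInterval]
    binding_sites: list[BindingSite] = field(default_factory=list)
    environment: dict[int, ResidueEnvironment] = field(default_factory=dict)
    rsa: dict[int, float] = field(default_factory=dict)
    rsa_threshold: float = DEFAULT_RSA_THRESHOLD

    def __post_init__(self):
        self._index = []  # sorted (start, end, name) over all segments
        for dom in self.domains:
            for s, e in dom.segments:
                if e > self.length:
                    raise AnnotationError(
                        f"domain {dom.name} segment ({s},{e}) exceeds length {self.length}"
                    )
                self._index.append((s, e, dom.name))
        self._index.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(self._index, self._index[1:]):
            if s2 <= e1:
                raise AnnotationError(f"domains {n1} and {n2} overlap at {s2}..{e1}")
        self._starts = [s for s, _, _ in self._index]
        by_name = {d.name: d for d in self.domains}
        for site in self.binding_sites:
            for r in site.residues:
                if not 1 <= r <= self.length:
                    raise AnnotationError(
                        f"site {site.name} residue {r} outside 1..{self.length}"
                    )
                if site.host_domain is not None:
                    host = by_name.get(site.host_domain)
                    if host is None:
                        raise AnnotationError(
                            f"site {site.name} host domain {site.host_domain!r} unknown"
                        )
                    if not host.contains(r):
                        raise AnnotationError(
                            f"site {site.name} residue {r} outside host {site.host_domain}"
                        )

    # -- queries -------------------------------------------------------------

    def locate_domain(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise PositionError(f"position {position} outside 1..{self.length}")
        i = bisect_right(self._starts, position) - 1
        if i >= 0:
            s, e, name = self._index[i]
            if s <= position <= e:
                return name
        return INTER_DOMAIN

    def classify_location(
        self, position: int, rsa_threshold: float | None = None
    ) -> ResidueEnvironment:
        """Explicit environment table wins; otherwise derive from RSA.

        In RSA mode a residue is buried iff rsa < threshold (default 0.20).
        """
        if not 1 <= position <= self.length:
            raise PositionError(f"position {position} outside 1..{self.length}")
        if position in self.environment:
            return self.environment[position]
        if position in self.rsa:
            thr = self.rsa_threshold if rsa_threshold is None else rsa_threshold
            rsa = self.rsa[position]
            cls = "buried" if rsa < thr else "surface"
            return ResidueEnvironment(position, cls, between_helices=False, rsa=rsa)
        raise MissingLocationError(
            f"no explicit location class or RSA for position {position}"
        )

    def binding_site_proximity(
        self, position: int, window: int = DEFAULT_PROXIMITY_WINDOW
    ) -> "ProximityResult":
        """Minimum sequence separation to any registered site residue.

        Distance 0 means the position is itself a site residue. An empty
        registry yields (False, None, inf).
        """
        best = math.inf
        best_site = None
        for site in self.binding_sites:
            d = min(abs(position - r) for r in site.residues)
            if d < best:
                best, best_site = d, site.name
        return ProximityResult(
            is_proximal=best <= window, nearest_site=best_site, distance=best
        )


class MissingLocationError(AnnotationError, KeyError):
    """Position lacks both an explicit class and an RSA value."""


@dataclass(frozen=True)
class ProximityResult:
    is_proximal: bool
    nearest_site: str | None
    distance: float  # residues; math.inf when no site registered


# --- module-level convenience wrappers (the spec's operation surface) -------

def locate_domain(position: int, annotation: ProteinAnnotation) -> str:
    return annotation.locate_domain(position)


def classify_location(
    position: int, annotation: ProteinAnnotation, rsa_threshold: float | None = None
) -> ResidueEnvironment:
    return annotation.classify_location(position, rsa_threshold)


def binding_site_proximity(
    position: int, annotation: ProteinAnnotation, window: int = DEFAULT_PROXIMITY_WINDOW
) -> ProximityResult:
    return annotation.binding_site_proximity(position, window)


# --- file formats -----------------------------------------------------------

def _residues_from_spec(spec) -> frozenset[int]:
    """Site residues given as ints and/or [start, end] intervals."""
    out: set[int] = set()
    for item in spec:
        if isinstance(item, (list, tuple)):
            s, e = item
            out.update(range(int(s), int(e) + 1))
        else:
            out.add(int(item))
    return frozenset(out)


def load_annotation(
    path: str | Path, environment_table: str | Path | None = None
) -> ProteinAnnotation:
    """Read a YAML annotation file (domains + binding sites), optionally with
    a per-residue environment TSV (columns: position, location_class, rsa, bh).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("protein", "length", "domains"):
        if key not in doc:
            raise AnnotationError(f"annotation file missing key {key!r}")
    domains = [
        DomainInterval(
            name=str(d["name"]),
            segments=tuple((int(s), int(e)) for s, e in d["segments"]),
        )
        for d in doc["domains"]
    ]
    sites = [
        BindingSite(
            name=str(s["name"]),
            residues=_residues_from_spec(s["residues"]),
            host_domain=s.get("host_domain"),
        )
        for s in doc.get("binding_sites", [])
    ]
    ann = ProteinAnnotation(
        protein=str(doc["protein"]),
        length=int(doc["length"]),
        domains=domains,
        binding_sites=sites,
        rsa_threshold=float(doc.get("rsa_threshold", DEFAULT_RSA_THRESHOLD)),
    )
    if environment_table is not None:
        env, rsa = load_environment_table(environment_table, ann.rsa_threshold)
        ann.environment.update(env)
        ann.rsa.update(rsa)
    return ann


def load_environment_table(
    path: str | Path, rsa_threshold: float = DEFAULT_RSA_THRESHOLD
) -> tuple[dict[int, ResidueEnvironment], dict[int, float]]:
    """Read a per-residue environment TSV.

    Columns: ``position`` (required), ``location_class`` (buried/surface,
    optional), ``rsa`` (optional), ``bh`` (0/1, optional). When both an
    explicit class and an RSA are present they must agree under the
    threshold.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in df.columns:
        raise AnnotationError(f"environment table {path} lacks 'position' column")
    env: dict[int, ResidueEnvironment] = {}
    rsa_map: dict[int, float] = {}
    for _, row in df.iterrows():
        pos = int(row["position"])
        rsa = None
        if "rsa" in df.columns and pd.notna(row.get("rsa")):
            rsa = float(row["rsa"])
            rsa_map[pos] = rsa
        cls = None
        if "location_class" in df.columns and pd.notna(row.get("location_class")):
            cls = str(row["location_class"]).strip().lower()
            if cls not in ("buried", "surface"):
                raise AnnotationError(f"unknown location class {cls!r} at {pos}")
        if cls is not None and rsa is not None:
            derived = "buried" if rsa < rsa_threshold else "surface"
            if derived != cls:
                raise AnnotationError(
                    f"position {pos}: class {cls} inconsistent with rsa {rsa} "
                    f"under threshold {rsa_threshold}"
                )
        bh = False
        if "bh" in df.columns and pd.notna(row.get("bh")):
            bh = bool(int(row["bh"]))
        if cls is not None:
            env[pos] = ResidueEnvironment(pos, cls, between_helices=bh, rsa=rsa)
    return env, rsa_map


def write_annotation(ann: ProteinAnnotation, path: str | Path) -> None:
    doc = {
        "protein": ann.protein,
        "length": ann.length,
        "rsa_threshold": ann.rsa_threshold,
        "domains": [
            {"name": d.name, "segments": [list(seg) for seg in d.segments]}
            for d in ann.domains
        ],
        "binding_sites": [
            {
                "name": s.name,
                "residues": sorted(s.residues),
                **({"host_domain": s.host_domain} if s.host_domain else {}),
            }
            for s in ann.binding_sites
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
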