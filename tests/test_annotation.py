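"""Domain lookup, location classification and binding-site proximity."""
import math

import pytest

from mutriage.annotation import (
    INTER_DOMAIN,
    BindingSite,
    DomainInterval,
    MissingLocationError,
    ProteinAnnotation,
    load_annotation,
    write_annotation,
)
from mutriage.errors import AnnotationError, PositionError


def test_bundled_annotation_inventory(bundle):
    names = [d.name for d in bundle.annotation.domains]
    assert names == [
        "F0", "F1", "F2", "F3", "linker",
        "R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9", "R10",
        "R11", "R12", "R13", "DD",
    ]
    r7 = next(d for d in bundle.annotation.domains if d.name == "R7")
    assert r7.segments == ((1352, 1457), (1585, 1659))  # discontinuous, wraps R8
    dd = next(d for d in bundle.annotation.domains if d.name == "DD")
    assert dd.segments == ((2494, 2541),)


@pytest.mark.parametrize(
    "position, domain",
    [(392, "F3"), (1539, "R8"), (2509, "DD"), (440, "linker"), (1600, "R7")],
)
def test_locate_domain(bundle, position, domain):
    assert bundle.annotation.locate_domain(position) == domain


def test_locate_domain_out_of_range(bundle):
    with pytest.raises(PositionError):
        bundle.annotation.locate_domain(0)
    with pytest.raises(PositionError):
        bundle.annotation.locate_domain(2542)


def test_all_catalog_positions_map_to_printed_domain(bundle, reference_rows):
    for mid, (domain, *_rest) in reference_rows.items():
        pos = int(mid[1:-1])
        assert bundle.annotation.locate_domain(pos) == domain, mid


def test_inter_domain_gap():
    ann = ProteinAnnotation(
        protein="toy", length=100,
        domains=[DomainInterval("A", ((1, 30),)), DomainInterval("B", ((60, 100),))],
    )
    assert ann.locate_domain(45) == INTER_DOMAIN


def test_classify_location_table_and_rsa_modes(bundle):
    env = bundle.annotation.classify_location(392)
    assert env.location_class == "buried" and not env.between_helices
    assert bundle.annotation.classify_location(229).between_helices

    ann = ProteinAnnotation(
        protein="toy", length=10, domains=[DomainInterval("A", ((1, 10),))],
        rsa={1: 0.0, 2: 1.0, 3: 0.19999, 4: 0.2},
    )
    assert ann.classify_location(1).location_class == "buried"
    assert ann.classify_location(2).location_class == "surface"
    assert ann.classify_location(3).location_class == "buried"  # just under threshold
    assert ann.classify_location(4).location_class == "surface"  # boundary is surface
    with pytest.raises(MissingLocationError):
        ann.classify_location(9)


def test_classify_location_monotone_in_rsa():
    """Lowering RSA never flips buried -> surface."""
    ann = ProteinAnnotation(
        protein="toy", length=21, domains=[DomainInterval("A", ((1, 21),))],
        rsa={i + 1: i / 20 for i in range(21)},
    )
    classes = [ann.classify_location(i + 1).location_class for i in range(21)]
    assert classes == sorted(classes, key=lambda c: c != "buried")


@pytest.mark.parametrize(
    "position, window, proximal, site, distance",
    [
        (1539, 10, True, "DLC-1", 5),
        (1770, 10, True, "autoinhibition", 0),
        (392, 10, True, "integrin", 0),
        (1000, 10, False, None, None),  # far from every registered site
    ],
)
def test_binding_site_proximity(bundle, position, window, proximal, site, distance):
    res = bundle.annotation.binding_site_proximity(position, window)
    assert res.is_proximal is proximal
    if proximal:
        assert (res.nearest_site, res.distance) == (site, distance)


def test_proximity_zero_iff_inside_site(bundle):
    sites = {r for s in bundle.annotation.binding_sites for r in s.residues}
    for pos in (1530, 1544, 392, 2300, 2541, 1539, 229):
        res = bundle.annotation.binding_site_proximity(pos)
        assert (res.distance == 0) == (pos in sites)


def test_empty_registry_returns_inf_sentinel():
    ann = ProteinAnnotation(
        protein="toy", length=50, domains=[DomainInterval("A", ((1, 50),))]
    )
    res = ann.binding_site_proximity(25)
    assert not res.is_proximal and res.nearest_site is None and math.isinf(res.distance)


def test_annotation_invariant_violations():
    with pytest.raises(AnnotationError):  # overlapping domains
        ProteinAnnotation(
            protein="x", length=100,
            domains=[DomainInterval("A", ((1, 50),)), DomainInterval("B", ((40, 90),))],
        )
    with pytest.raises(AnnotationError):  # site residue outside host domain
        ProteinAnnotation(
            protein="x", length=100, domains=[DomainInterval("A", ((1, 50),))],
            binding_sites=[BindingSite("s", frozenset({60}), host_domain="A")],
        )
    with pytest.raises(AnnotationError):  # site residue beyond sequence
        ProteinAnnotation(
            protein="x", length=100, domains=[DomainInterval("A", ((1, 50),))],
            binding_sites=[BindingSite("s", frozenset({9999}))],
        )


def test_annotation_yaml_roundtrip(bundle, tmp_path):
    out = tmp_path / "ann.yaml"
    write_annotation(bundle.annotation, out)
    back = load_annotation(out)
    assert [d.name for d in back.domains] == [d.name for d in bundle.annotation.domains]
    assert {s.name: s.residues for s in back.binding_sites} == {
        s.name: s.residues for s in bundle.annotation.binding_sites
    }
    assert back.locate_domain(1539) == "R8"
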