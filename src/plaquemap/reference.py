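"""Curated reference panel of plaque-associated lipid species.

The panel lists the sphingolipid and glycerophospholipid species that have
been verified by high-mass-resolution MALDI orbitrap imaging to be enriched
or depleted around amyloid-beta plaques in human cortex, together with
their literature neutral monoisotopic masses and the observed [M-H]- m/z
values from both a MALDI-TOF and an orbitrap instrument.

Notes on individual rows:

* Single-chain PA/PE/PI entries are lyso species; their canonical names
  carry the L prefix (e.g. ``PI(20:4)`` -> ``LPI(20:4)``).
* The row published as ``LPA(18:0)`` carries the mass of cyclic
  phosphatidic acid and is canonically ``CPA(18:0)`` (the species reported
  in the tissue), with the published spelling kept as an alias.
* ``LPI(20:4)``: the literature theoretical mass (620.1377) is a typo; the
  computed value is 620.2962 and the observed orbitrap m/z is consistent
  with it. Flagged ``theor_mass_typo`` and excluded from mass regression.
* ``PA(16:0/18:1)``: the literature theoretical mass corresponds to a 34:2
  species and the row is internally inconsistent. Flagged ``inconsistent``
  and excluded from both the mass regression set and the default library.
* The MALDI-TOF observed column contains typographically truncated entries
  (e.g. ``120.763``); it is retained verbatim as metadata only and is never
  used for matching.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferenceSpecies",
    "REFERENCE_PANEL",
    "clean_mass_rows",
    "library_names",
    "orbitrap_observed",
]


@dataclass(frozen=True)
class ReferenceSpecies:
    lipid_class: str
    published_name: str
    canonical_name: str
    neutral_mass_reported: float
    observed_mz_tof: float | None
    observed_mz_orbitrap: float | None
    flags: tuple[str, ...] = ()


def _r(cls, published, canonical, theo, tof, orbi, *flags):
    return ReferenceSpecies(cls, published, canonical, theo, tof, orbi, tuple(flags))


#: All published rows, in published order.
REFERENCE_PANEL: tuple[ReferenceSpecies, ...] = (
    _r("CerP", "CerP(d18:1/16:0)", "CerP(d18:1/16:0)", 617.4784, 616.453, 616.4712),
    _r("CerP", "CerP(d18:1/18:0)", "CerP(d18:1/18:0)", 645.5097, 644.421, 644.5025),
    _r("CerP", "CerP(d18:1/20:0)", "CerP(d18:1/20:0)", 673.5410, 672.483, 672.5339),
    _r("Cer-PE", "PE-Cer(36:1)", "PE-Cer(36:1)", 688.5519, 687.496, 687.5443),
    _r("Cer-PE", "PE-Cer(38:1)", "PE-Cer(38:1)", 716.5832, 715.565, 715.5757),
    _r("Cer-PE", "PE-Cer(40:1)", "PE-Cer(40:1)", 744.6145, 743.509, 743.6070),
    _r("GM", "GM3(d18:1/18:0)", "GM3(d18:1/18:0)", 1180.7445, 1179.599, 1179.7366),
    _r("GM", "GM3(d18:1/20:0)", "GM3(d18:1/20:0)", 1208.7758, 120.763, 1207.7683,
       "tof_truncated"),
    _r("GM", "GM2(d18:1/18:0)", "GM2(d18:1/18:0)", 1383.8238, 1382.717, 1382.8153),
    _r("GM", "GM2(d18:1/20:0)", "GM2(d18:1/20:0)", 1411.8551, 1410.756, 1410.8457),
    _r("GM", "GM1(d18:1/18:0)", "GM1(d18:1/18:0)", 1545.8767, 1544.733, 1544.8679),
    _r("GM", "GM1(d18:1/20:0)", "GM1(d18:1/20:0)", 1573.9080, 1572.818, 1572.8992),
    _r("HexCer", "HexCer(d18:1/12:0)", "HexCer(d18:1/12:0)", 643.5023, 642.394, None),
    _r("HexCer", "HexCer(18:1/14:0)", "HexCer(d18:1/14:0)", 671.5336, 670.464, None),
    _r("PA", "LPA(18:0)", "CPA(18:0)", 420.2641, 419.251, 419.2569, "cpa_alias"),
    _r("PA", "PA(16:0/16:0)", "PA(16:0/16:0)", 648.4730, 647.445, None),
    _r("PA", "PA(16:0/18:1)", "PA(16:0/18:1)", 672.4730, 673.441, 673.4813,
       "inconsistent"),
    _r("PA", "PA(18:0/22:6)", "PA(18:0/22:6)", 748.5043, 747.469, 747.4970),
    _r("PE", "PE(18:0)", "LPE(18:0)", 481.3168, 480.245, 480.3096),
    _r("PE", "PE(22:6)", "LPE(22:6)", 525.2855, 524.247, 524.2785),
    _r("PE", "PE(18:1/18:0)", "PE(18:1/18:0)", 745.5622, 744.523, 744.5548),
    _r("PE", "PE(18:1/20:0)", "PE(18:1/20:0)", 773.5935, 772.467, None),
    _r("PE", "PE(P-18:0/20:4)", "PE(P-18:0/20:4)", 751.5516, 750.525, 750.5444),
    _r("PE", "PE(18:0/20:4)", "PE(18:0/20:4)", 767.5465, 766.559, 766.5395),
    _r("PE", "PE(16:0/22:6)", "PE(16:0/22:6)", 763.5152, 762.403, 762.5078),
    _r("PE", "PE(P-18:0/22:6)", "PE(P-18:0/22:6)", 775.5516, 77.447, 774.5444,
       "tof_truncated"),
    _r("PE", "PE(18:0/22:6)", "PE(18:0/22:6)", 791.5465, 790.449, 790.5392),
    _r("PI", "PI(16:0)", "LPI(16:0)", 572.2962, 571.242, None),
    _r("PI", "PI(18:0)", "LPI(18:0)", 600.3275, 599.274, 599.3203),
    _r("PI", "PI(20:4)", "LPI(20:4)", 620.1377, 619.258, 619.2890, "theor_mass_typo"),
    _r("PI", "PI(16:0/20:4)", "PI(16:0/20:4)", 858.5258, 857.414, 857.5185),
    _r("PI", "PI(18:0/20:4)", "PI(18:0/20:4)", 886.5571, 885.468, None),
    _r("ST", "ST(d18:1/22:0)", "ST(d18:1/22:0)", 863.6156, 862.513, 862.6080),
    _r("ST", "ST(d18:1/22:0(2OH))", "ST(d18:1/22:0(2OH))", 879.6106, 878.539, 878.6033),
    _r("ST", "ST(d18:1/24:1)", "ST(d18:1/24:1)", 889.6313, 88.854, 888.6238,
       "tof_truncated"),
    _r("ST", "ST(d18:1/24:0)", "ST(d18:1/24:0)", 891.6469, 890.559, 890.6398),
    _r("ST", "ST(d18:1/24:1(2OH))", "ST(d18:1/24:1(2OH))", 905.6262, 904.543, 904.6187),
    _r("ST", "ST(d18:1/24:0(2OH))", "ST(d18:1/24:0(2OH))", 907.6419, 90.657, 906.6346,
       "tof_truncated"),
)


def clean_mass_rows() -> list[ReferenceSpecies]:
    """Rows whose reported neutral mass is internally consistent (36 rows)."""
    bad = {"theor_mass_typo", "inconsistent"}
    return [r for r in REFERENCE_PANEL if not (set(r.flags) & bad)]


def library_names() -> list[str]:
    """Canonical names to build the default annotation library from.

    The internally inconsistent ``PA(16:0/18:1)`` row is excluded.
    """
    return [r.canonical_name for r in REFERENCE_PANEL if "inconsistent" not in r.flags]


def orbitrap_observed(include_inconsistent: bool = True) -> list[float]:
    """The observed orbitrap [M-H]- m/z values (query peaks for annotation)."""
    out = []
    for r in REFERENCE_PANEL:
        if r.observed_mz_orbitrap is None:
            continue
        if not include_inconsistent and "inconsistent" in r.flags:
            continue
        out.append(r.observed_mz_orbitrap)
    return out
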