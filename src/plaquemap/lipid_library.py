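"""Shorthand lipid nomenclature, monoisotopic masses and accurate-mass matching.

This module turns shorthand lipid names such as ``ST(d18:1/24:0(2OH))`` or
``PE(P-18:0/22:6)`` into molecular formulas, computes neutral monoisotopic
masses and deprotonated ([M-H]-) m/z values, and matches observed peaks
against a species library at a parts-per-million tolerance.

Supported classes are the sphingolipids built on a ceramide backbone
(CerP, PE-Cer, HexCer, ST, GM1/GM2/GM3) and the glycerophospholipids
PA/PE/PI together with their lyso (L-), cyclic (CPA) and plasmalogen (P-)
variants -- the classes relevant to negative-ion-mode brain lipid imaging.
"""

from __future__ import annotations

import bisect
import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ElementCounts",
    "ChainSpec",
    "LipidSpecies",
    "LibraryEntry",
    "MassLibrary",
    "AnnotationHit",
    "LipidNameError",
    "FormulaError",
    "parse_lipid_name",
    "build_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "match_peaks",
    "best_hits",
    "write_annotation_csv",
]

#: Monoisotopic element masses in Da (12C scale).
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of a proton in Da, electron-corrected. At m/z above ~500 the
#: electron mass (5.5e-4 Da) already exceeds a 1 ppm error budget, so the
#: deprotonated adduct must subtract the proton, not the hydrogen atom.
PROTON_MASS = 1.00727646


class LipidNameError(ValueError):
    """A shorthand name does not follow the supported grammar."""


class FormulaError(ValueError):
    """A formula operation produced an invalid (e.g. negative) composition."""


@dataclass(frozen=True)
class ElementCounts:
    """Immutable element-count vector (a molecular formula).

    Supports element-wise addition and subtraction; subtraction raises
    :class:`FormulaError` if any count would become negative.
    """

    counts: tuple[tuple[str, int], ...]

    @staticmethod
    def make(**counts: int) -> "ElementCounts":
        return ElementCounts.from_dict(counts)

    @staticmethod
    def from_dict(counts: Mapping[str, int]) -> "ElementCounts":
        for el, n in counts.items():
            if el not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n > 0))
        return ElementCounts(items)

    @staticmethod
    def from_formula(formula: str) -> "ElementCounts":
        """Parse a plain formula string such as ``"C36H71NO3"``."""
        if not formula:
            return ElementCounts(())
        out: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if m.start() != pos or not m.group(0):
                break
            el, num = m.group(1), m.group(2)
            if el not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {el!r} in {formula!r}")
            out[el] = out.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
            if pos == len(formula):
                return ElementCounts.from_dict(out)
        raise FormulaError(f"cannot parse formula {formula!r}")

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return ElementCounts.from_dict(out)

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        out = self.as_dict()
        for el, n in other.counts:
            res = out.get(el, 0) - n
            if res < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count ({out.get(el, 0)} - {n})"
                )
            out[el] = res
        return ElementCounts.from_dict(out)

    def __mul__(self, k: int) -> "ElementCounts":
        if k < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return ElementCounts.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Formula in Hill order (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(d):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)


def monoisotopic_mass(formula: ElementCounts) -> float:
    """Neutral monoisotopic mass of *formula* in Da (0.0 for the empty formula)."""
    return sum(n * ELEMENT_MASSES[el] for el, n in formula.counts)


# --- residue building blocks ------------------------------------------------

_WATER = ElementCounts.make(H=2, O=1)
_OXYGEN = ElementCounts.make(O=1)
_HPO3 = ElementCounts.make(H=1, P=1, O=3)
_SO3 = ElementCounts.make(S=1, O=3)
_HEXOSE = ElementCounts.make(C=6, H=10, O=5)           # anhydro hexose residue
_HEXNAC = ElementCounts.make(C=8, H=13, N=1, O=5)      # anhydro HexNAc residue
_NEUAC = ElementCounts.make(C=11, H=17, N=1, O=8)      # anhydro NeuAc residue
_PEA = ElementCounts.make(C=2, H=6, N=1, O=3, P=1)     # phosphoethanolamine headgroup
_ETHANOLAMINE_N = ElementCounts.make(C=2, H=5, N=1)    # PE = PA + C2H5N

_SPHINGO_CLASSES = frozenset({"CerP", "PE-Cer", "HexCer", "ST", "GM1", "GM2", "GM3"})
_GLYCERO_CLASSES = frozenset({"PA", "LPA", "CPA", "PE", "LPE", "PE-P", "PI", "LPI"})
SUPPORTED_CLASSES = _SPHINGO_CLASSES | _GLYCERO_CLASSES


@dataclass(frozen=True)
class ChainSpec:
    """A fatty chain: carbon count, double bonds and an optional prefix.

    ``prefix`` is ``"d"`` for a dihydroxy sphingoid base and ``"P"`` for a
    plasmalogen (1Z-alkenyl / vinyl-ether) chain; ``None`` for a plain acyl.
    """

    carbons: int
    double_bonds: int
    prefix: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LipidNameError(f"chain needs >= 2 carbons, got {self.carbons}")
        if not (0 <= self.double_bonds <= self.carbons // 2):
            raise LipidNameError(
                f"double bonds {self.double_bonds} out of range for "
                f"{self.carbons} carbons"
            )

    def __str__(self) -> str:
        p = {"d": "d", "P": "P-"}.get(self.prefix or "", "")
        return f"{p}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species with its formula and neutral monoisotopic mass."""

    shorthand_name: str
    lipid_class: str
    chain1: ChainSpec
    chain2: ChainSpec | None = None
    hydroxylated: bool = False
    formula: ElementCounts = field(default_factory=lambda: ElementCounts(()))
    neutral_mass: float = 0.0

    @property
    def sphingoid_or_sn1(self) -> ChainSpec:
        return self.chain1

    @property
    def sn2_or_acyl(self) -> ChainSpec | None:
        return self.chain2


_CHAIN_RE = re.compile(r"^(d|P-)?(\d+):(\d+)$")


def _parse_chain(token: str) -> ChainSpec:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidNameError(f"cannot parse chain token {token!r}")
    prefix = {"d": "d", "P-": "P"}.get(m.group(1) or "")
    return ChainSpec(int(m.group(2)), int(m.group(3)), prefix or None)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepted spellings include explicit sphingoid backbones
    (``ST(d18:1/24:0)``), sum compositions that imply a d18:1 backbone
    (``PE-Cer(36:1)``, ``HexCer(18:1/14:0)``), hydroxylated acyls
    (``...(2OH)``), plasmalogens (``PE(P-18:0/22:6)``), and single-chain
    glycerophospholipids, which are normalised to lyso species
    (``PI(20:4)`` -> ``LPI(20:4)``). ``Cer-PE`` is accepted as an alias of
    ``PE-Cer``, ``LPA(18:0)`` of ``CPA(18:0)`` only via explicit class names.
    """
    raw = name
    name = name.replace(" ", "").replace("−", "-")
    m = re.match(r"^([A-Za-z0-9-]+)\((.+)\)$", name)
    if not m:
        raise LipidNameError(f"cannot parse lipid name {raw!r}")
    cls, inner = m.group(1), m.group(2)
    if cls == "Cer-PE":
        cls = "PE-Cer"
    hydroxylated = False
    if inner.endswith("(2OH)"):
        hydroxylated = True
        inner = inner[: -len("(2OH)")]
    tokens = inner.split("/")
    if len(tokens) > 2 or not tokens[0]:
        raise LipidNameError(f"cannot parse chain specification {inner!r} in {raw!r}")
    chains = [_parse_chain(t) for t in tokens]

    if cls in _SPHINGO_CLASSES:
        if len(chains) == 1:
            # sum composition: total carbons/double bonds on an implied d18:1 base
            total = chains[0]
            if total.prefix is not None:
                raise LipidNameError(
                    f"single-chain sphingolipid {raw!r} must be a sum composition"
                )
            if total.carbons <= 18 or total.double_bonds < 1:
                raise LipidNameError(
                    f"sum composition {total} too small for a d18:1 backbone"
                )
            chain1 = ChainSpec(18, 1, "d")
            chain2 = ChainSpec(total.carbons - 18, total.double_bonds - 1)
        else:
            chain1, chain2 = chains
            if chain1.prefix is None:
                # tolerate the shorthand "HexCer(18:1/14:0)" for d18:1
                chain1 = replace(chain1, prefix="d")
            if chain1.prefix != "d" or chain2.prefix is not None:
                raise LipidNameError(f"unsupported chain prefixes in {raw!r}")
    elif cls in _GLYCERO_CLASSES or cls in {"PA", "PE", "PI"}:
        if len(chains) == 1:
            chain1, chain2 = chains[0], None
            if chain1.prefix is not None:
                raise LipidNameError(f"unsupported chain prefix in lyso species {raw!r}")
            if cls in {"PA", "PE", "PI"}:
                cls = "L" + cls  # printed single-chain PA/PE/PI are lyso species
            elif cls in {"LPA", "LPE", "LPI", "CPA"}:
                pass
            else:
                raise LipidNameError(f"class {cls!r} requires two chains in {raw!r}")
        else:
            chain1, chain2 = chains
            if chain1.prefix == "P":
                if cls != "PE":
                    raise LipidNameError(
                        f"plasmalogen prefix only supported for PE, got {raw!r}"
                    )
                cls = "PE-P"
            elif chain1.prefix is not None or chain2.prefix is not None:
                raise LipidNameError(f"unsupported chain prefixes in {raw!r}")
            if cls in {"LPA", "LPE", "LPI", "CPA"}:
                raise LipidNameError(f"class {cls!r} takes a single chain in {raw!r}")
    else:
        raise LipidNameError(
            f"unsupported lipid class {cls!r} (supported: "
            f"{', '.join(sorted(SUPPORTED_CLASSES))})"
        )

    species = LipidSpecies(
        shorthand_name=raw.strip(),
        lipid_class=cls,
        chain1=chain1,
        chain2=chain2,
        hydroxylated=hydroxylated,
    )
    formula = build_formula(species)
    return replace(species, formula=formula, neutral_mass=monoisotopic_mass(formula))


def _ceramide(sphingoid: ChainSpec, acyl: ChainSpec) -> ElementCounts:
    """Ceramide = dihydroxy sphingoid base + fatty acid - H2O.

    For the d18:1 base this reduces to C(18+X) H(35+2X-2Y) N O3 for an
    X:Y N-acyl chain.
    """
    if sphingoid.prefix != "d":
        raise FormulaError("ceramide backbone requires a d-prefixed sphingoid base")
    s, b = sphingoid.carbons, sphingoid.double_bonds
    base = ElementCounts.make(C=s, H=2 * s + 3 - 2 * b, N=1, O=2)
    x, y = acyl.carbons, acyl.double_bonds
    fatty_acid = ElementCounts.make(C=x, H=2 * x - 2 * y, O=2)
    return base + fatty_acid - _WATER


def _pa(carbons: int, double_bonds: int, lyso: bool = False) -> ElementCounts:
    """(Lyso)phosphatidic acid with the given total chain composition."""
    c, d = carbons, double_bonds
    if lyso:
        return ElementCounts.make(C=c + 3, H=2 * c + 7 - 2 * d, O=7, P=1)
    return ElementCounts.make(C=c + 3, H=2 * c + 5 - 2 * d, O=8, P=1)


def build_formula(species: LipidSpecies) -> ElementCounts:
    """Molecular formula of a parsed species from per-class construction rules."""
    cls = species.lipid_class
    c1, c2 = species.chain1, species.chain2

    if cls in _SPHINGO_CLASSES:
        assert c2 is not None
        cer = _ceramide(c1, c2)
        if cls == "CerP":
            formula = cer + _HPO3
        elif cls == "PE-Cer":
            formula = cer + _PEA
        elif cls == "HexCer":
            formula = cer + _HEXOSE
        elif cls == "ST":
            formula = cer + _HEXOSE + _SO3
        elif cls == "GM3":
            formula = cer + 2 * _HEXOSE + _NEUAC
        elif cls == "GM2":
            formula = cer + 2 * _HEXOSE + _NEUAC + _HEXNAC
        else:  # GM1
            formula = cer + 3 * _HEXOSE + _NEUAC + _HEXNAC
    elif cls in {"PA", "PE", "PI"}:
        assert c2 is not None
        total_c = c1.carbons + c2.carbons
        total_d = c1.double_bonds + c2.double_bonds
        formula = _pa(total_c, total_d)
        if cls == "PE":
            formula = formula + _ETHANOLAMINE_N
        elif cls == "PI":
            formula = formula + _HEXOSE
    elif cls == "PE-P":
        assert c2 is not None
        total_c = c1.carbons + c2.carbons
        total_d = c1.double_bonds + c2.double_bonds
        formula = _pa(total_c, total_d) + _ETHANOLAMINE_N - _OXYGEN
    elif cls in {"LPA", "LPE", "LPI", "CPA"}:
        formula = _pa(c1.carbons, c1.double_bonds, lyso=True)
        if cls == "LPE":
            formula = formula + _ETHANOLAMINE_N
        elif cls == "LPI":
            formula = formula + _HEXOSE
        elif cls == "CPA":
            formula = formula - _WATER
    else:  # pragma: no cover - guarded by the parser
        raise FormulaError(f"no construction rule for class {cls!r}")

    if species.hydroxylated:
        formula = formula + _OXYGEN
    return formula


_ADDUCT_ALIASES = {
    "[M-H]-": "[M-H]-",
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M - H]-": "[M-H]-",
    "M-H": "[M-H]-",
}

SUPPORTED_ADDUCTS = ("[M-H]-",)


def adduct_mz(neutral_mass: float, adduct: str = "[M-H]-") -> float:
    """m/z of *neutral_mass* under the given adduct (deprotonation only)."""
    canonical = _ADDUCT_ALIASES.get(adduct.replace(" ", ""), None)
    if canonical != "[M-H]-":
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {', '.join(SUPPORTED_ADDUCTS)}"
        )
    if neutral_mass <= PROTON_MASS:
        raise ValueError(
            f"neutral mass {neutral_mass} Da cannot lose a proton and stay positive"
        )
    return neutral_mass - PROTON_MASS


@dataclass(frozen=True)
class LibraryEntry:
    species: LipidSpecies
    adduct: str
    mz: float


@dataclass(frozen=True)
class AnnotationHit:
    observed_mz: float
    species: str
    adduct: str
    theoretical_mz: float
    ppm_error: float  # 1e6 * (observed - theoretical) / theoretical


class MassLibrary:
    """A set of (species, adduct, m/z) entries sorted by adduct m/z."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        entries = sorted(entries, key=lambda e: e.mz)
        seen = set()
        for e in entries:
            key = (e.species.shorthand_name, e.adduct)
            if key in seen:
                raise ValueError(f"duplicate library entry {key}")
            seen.add(key)
        self.entries: list[LibraryEntry] = entries
        self._mzs = [e.mz for e in entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_names(
        cls, names: Iterable[str], adducts: Sequence[str] = ("[M-H]-",)
    ) -> "MassLibrary":
        entries = []
        for name in names:
            sp = parse_lipid_name(name)
            for adduct in adducts:
                entries.append(LibraryEntry(sp, "[M-H]-", adduct_mz(sp.neutral_mass, adduct)))
        return cls(entries)

    @classmethod
    def from_species_csv(cls, path) -> "MassLibrary":
        """Load a species panel CSV with columns ``name[,class,formula,neutral_mass]``.

        When a formula or neutral mass is given it overrides the parsed value
        (after a consistency check at 1e-3 Da when both are derivable).
        """
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "name" not in reader.fieldnames:
                raise ValueError(f"{path}: species CSV needs a 'name' column")
            for row in reader:
                name = row["name"].strip()
                formula_txt = (row.get("formula") or "").strip()
                mass_txt = (row.get("neutral_mass") or "").strip()
                if formula_txt:
                    formula = ElementCounts.from_formula(formula_txt)
                    mass = monoisotopic_mass(formula)
                    cls_name = (row.get("class") or "").strip() or "unknown"
                    sp = LipidSpecies(
                        shorthand_name=name,
                        lipid_class=cls_name,
                        chain1=ChainSpec(2, 0),
                        formula=formula,
                        neutral_mass=mass,
                    )
                elif mass_txt:
                    mass = float(mass_txt)
                    sp = LipidSpecies(
                        shorthand_name=name,
                        lipid_class=(row.get("class") or "").strip() or "unknown",
                        chain1=ChainSpec(2, 0),
                        neutral_mass=mass,
                    )
                else:
                    sp = parse_lipid_name(name)
                entries.append(
                    LibraryEntry(sp, "[M-H]-", adduct_mz(sp.neutral_mass, "[M-H]-"))
                )
        return cls(entries)


def match_peaks(
    observed: Sequence[float], library: MassLibrary, tol_ppm: float = 2.0
) -> list[AnnotationHit]:
    """All library hits within ``tol_ppm`` for each observed m/z.

    Hits are grouped by observed peak (in input order) and, within a peak,
    ordered by increasing absolute ppm error with lexicographic species-name
    tie-break. An empty result is not an error; an empty *library* is.
    """
    if len(library) == 0:
        raise ValueError("cannot match against an empty library")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    hits: list[AnnotationHit] = []
    mzs = library._mzs
    for obs in observed:
        half_width = obs * tol_ppm * 1e-6
        lo = bisect.bisect_left(mzs, obs - half_width)
        hi = bisect.bisect_right(mzs, obs + half_width)
        local = []
        for entry in library.entries[lo:hi]:
            ppm = 1e6 * (obs - entry.mz) / entry.mz
            if abs(ppm) <= tol_ppm:
                local.append(
                    AnnotationHit(obs, entry.species.shorthand_name, entry.adduct, entry.mz, ppm)
                )
        local.sort(key=lambda h: (abs(h.ppm_error), h.species))
        hits.extend(local)
    return hits


def best_hits(
    observed: Sequence[float], library: MassLibrary, tol_ppm: float = 2.0
) -> dict[float, AnnotationHit]:
    """Best hit (smallest |ppm error|) per observed peak; unmatched peaks absent."""
    out: dict[float, AnnotationHit] = {}
    for hit in match_peaks(observed, library, tol_ppm):
        if hit.observed_mz not in out:
            out[hit.observed_mz] = hit
    return out


def write_annotation_csv(hits: Iterable[AnnotationHit], path) -> None:
    """Write an annotation report CSV (observed_mz, species, adduct, ...)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["observed_mz", "species", "adduct", "theoretical_mz", "ppm_error"])
        for h in hits:
            writer.writerow(
                [f"{h.observed_mz:.9g}", h.species, h.adduct, f"{h.theoretical_mz:.9g}",
                 f"{h.ppm_error:.6f}"]
            )
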