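"""Seeded generator of schema-valid synthetic trait tables.

The generator emulates the structure of a compiled phytoplankton trait
table: nine groups in configurable proportions (defaults close to a
chlorophyte-dominated French lake taxa list), cell/colony/filament life
forms, a geometric form drawn from group-typical shape pools with
log-uniform linear dimensions, and group-conditional qualitative traits
drawn so that every consistency cross-check R1-R15 passes by
construction (cyanobacteria get no plastids and phycobilin, diatoms get a
siliceous skeleton and no flagellum, cryptophytes always carry a
flagellum, ...).  Biovolumes are computed from the drawn shape and
dimensions through the geometry module and the derived traits through the
derive module, so a generated table is a fixed point of
:func:`phytotraits.derive.derive_traits`.

Group allocation uses largest-remainder quotas, not multinomial draws, so
requested compositions are hit exactly.  :func:`inject_violation` applies
a minimal, surgical mutation that makes exactly one rule fail on one
record, for sensitivity testing of the rule engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import derive, geometry
from .qc import DEFAULT_PIGMENT_MATRIX, TOXIN_FAMILIES
from .schema import GROUPS, TraitTable, default_schema, make_taxa_code

__all__ = [
    "SynthConfig",
    "generate_table",
    "inject_violation",
    "generate_occurrences",
]

#: Default group composition (weights; chlorophyte-dominated lake list).
DEFAULT_GROUP_WEIGHTS: dict[str, float] = {
    "chlorophytes": 0.365,
    "cyanobacteria": 0.150,
    "diatoms": 0.160,
    "chrysophytes": 0.110,
    "xanthophytes": 0.045,
    "dinophytes": 0.050,
    "euglenophytes": 0.050,
    "cryptophytes": 0.022,
    "haptophytes": 0.048,
}

#: Default primary life-form weights (cell-dominated).
DEFAULT_LIFE_FORM_WEIGHTS: dict[str, float] = {
    "cell": 0.568,
    "colony": 0.329,
    "filament": 0.103,
}

#: Log-uniform range (µm) of the base linear size per group, chosen so the
#: pico...meso / pico...macro size classes all occur at moderate n.
DEFAULT_SIZE_RANGES: dict[str, tuple[float, float]] = {
    "chlorophytes": (1.0, 80.0),
    "cyanobacteria": (0.8, 60.0),
    "diatoms": (3.0, 200.0),
    "chrysophytes": (2.0, 50.0),
    "xanthophytes": (2.0, 60.0),
    "dinophytes": (8.0, 150.0),
    "euglenophytes": (10.0, 120.0),
    "cryptophytes": (4.0, 30.0),
    "haptophytes": (2.0, 20.0),
}

_SHAPE_POOLS: dict[str, tuple[str, ...]] = {
    "chlorophytes": ("sphere", "rotational_ellipsoid", "oval_cylinder", "tetrahedron"),
    "cyanobacteria": ("sphere", "cylinder"),
    "diatoms": ("cylinder", "parallelepiped", "prism_on_parallelogram_base",
                "prism_on_triangular_base", "cymbelloid", "oval_cylinder"),
    "chrysophytes": ("sphere", "rotational_ellipsoid", "cone_with_half_sphere"),
    "xanthophytes": ("cylinder", "rotational_ellipsoid", "tetrahedron"),
    "dinophytes": ("ceratium", "sphere", "rotational_ellipsoid", "flattened_ellipsoid"),
    "euglenophytes": ("rotational_ellipsoid", "double_cone", "cylinder",
                      "flattened_ellipsoid"),
    "cryptophytes": ("rotational_ellipsoid", "flattened_ellipsoid",
                     "cone_with_half_sphere"),
    "haptophytes": ("sphere", "rotational_ellipsoid"),
}
_DESMID_SHAPES = ("staurastrum", "double_cone")

# (genus, family) pools; fixed higher taxonomy per group.
_TAXONOMY: dict[str, dict] = {
    "chlorophytes": {
        "phylum": "Chlorophyta", "class": "Chlorophyceae", "order": "Sphaeropleales",
        "genera": [
            ("Scenedesmus", "Scenedesmaceae"), ("Chlorella", "Chlorellaceae"),
            ("Pediastrum", "Hydrodictyaceae"), ("Monoraphidium", "Selenastraceae"),
            ("Tetraedron", "Hydrodictyaceae"), ("Oocystis", "Oocystaceae"),
            ("Cosmarium", "Desmidiaceae"), ("Staurastrum", "Desmidiaceae"),
            ("Closterium", "Closteriaceae"),
        ],
    },
    "cyanobacteria": {
        "phylum": "Cyanobacteria", "class": "Cyanophyceae", "order": "Chroococcales",
        "genera": [
            ("Microcystis", "Microcystaceae"), ("Dolichospermum", "Aphanizomenonaceae"),
            ("Planktothrix", "Microcoleaceae"), ("Aphanizomenon", "Aphanizomenonaceae"),
            ("Chroococcus", "Chroococcaceae"), ("Merismopedia", "Merismopediaceae"),
        ],
    },
    "diatoms": {
        "phylum": "Bacillariophyta", "class": "Bacillariophyceae", "order": "Naviculales",
        "genera": [
            ("Navicula", "Naviculaceae"), ("Cyclotella", "Stephanodiscaceae"),
            ("Fragilaria", "Fragilariaceae"), ("Aulacoseira", "Aulacoseiraceae"),
            ("Nitzschia", "Bacillariaceae"), ("Asterionella", "Fragilariaceae"),
            ("Cymbella", "Cymbellaceae"),
        ],
    },
    "chrysophytes": {
        "phylum": "Ochrophyta", "class": "Chrysophyceae", "order": "Chromulinales",
        "genera": [
            ("Dinobryon", "Dinobryaceae"), ("Mallomonas", "Synuraceae"),
            ("Synura", "Synuraceae"), ("Chromulina", "Chromulinaceae"),
            ("Uroglena", "Ochromonadaceae"),
        ],
    },
    "xanthophytes": {
        "phylum": "Ochrophyta", "class": "Xanthophyceae", "order": "Mischococcales",
        "genera": [
            ("Ophiocytium", "Ophiocytiaceae"), ("Goniochloris", "Pleurochloridaceae"),
            ("Tetraplektron", "Pleurochloridaceae"), ("Centritractus", "Centritractaceae"),
        ],
    },
    "dinophytes": {
        "phylum": "Miozoa", "class": "Dinophyceae", "order": "Gonyaulacales",
        "genera": [
            ("Ceratium", "Ceratiaceae"), ("Peridinium", "Peridiniaceae"),
            ("Gymnodinium", "Gymnodiniaceae"), ("Parvodinium", "Peridiniaceae"),
        ],
    },
    "euglenophytes": {
        "phylum": "Euglenozoa", "class": "Euglenophyceae", "order": "Euglenales",
        "genera": [
            ("Euglena", "Euglenaceae"), ("Phacus", "Phacaceae"),
            ("Trachelomonas", "Euglenaceae"), ("Lepocinclis", "Phacaceae"),
        ],
    },
    "cryptophytes": {
        "phylum": "Cryptophyta", "class": "Cryptophyceae", "order": "Cryptomonadales",
        "genera": [
            ("Cryptomonas", "Cryptomonadaceae"), ("Rhodomonas", "Pyrenomonadaceae"),
            ("Plagioselmis", "Pyrenomonadaceae"),
        ],
    },
    "haptophytes": {
        "phylum": "Haptophyta", "class": "Coccolithophyceae", "order": "Prymnesiales",
        "genera": [
            ("Chrysochromulina", "Chrysochromulinaceae"),
            ("Prymnesium", "Prymnesiaceae"),
        ],
    },
}

_EPITHETS = (
    "aeruginosa", "minima", "gracile", "tenuis", "acuminatum", "limneticum",
    "viridis", "parvum", "elegans", "obtusa", "lacustris", "pusilla",
    "ovata", "rotunda", "curvatum", "longispina", "breve", "crassa",
    "granulata", "spinosum", "variabile", "commune", "dubium", "rectum",
    "sociale", "planctonicum", "fluviatile", "maximum", "minutum", "simplex",
    "ornatum", "erosa", "caudata", "hirundinella", "quadricauda", "armatum",
)

_REPRODUCTION = ("asexual", "sexual", "binary fission", "fragmentation",
                 "zoospores", "autospores", "oogamy")
_TOLERANCE = ("low light", "high temperature", "mixing", "nutrient deficiency",
              "grazing", "stratification")
_REYNOLDS = ("A", "B", "C", "D", "E", "F", "G", "H1", "J", "K", "Lo", "M",
             "N", "P", "S1", "T", "W1", "X1", "X2", "X3", "Y")
_WATER_TROPHY = ("oligotrophic", "oligo-mesotrophic", "mesotrophic",
                 "meso-eutrophic", "eutrophic", "hypereutrophic")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic trait-table generator."""

    n_taxa: int = 200
    group_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS))
    life_form_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFE_FORM_WEIGHTS))
    size_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    violations: Sequence[tuple[str, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if any(w < 0 for w in self.group_weights.values()):
            raise ValueError("group weights must be nonnegative")
        if sum(self.group_weights.values()) <= 0:
            raise ValueError("group weights must have a positive sum")
        unknown = set(self.group_weights) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in weights: {sorted(unknown)}")


def _largest_remainder(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Integer quotas summing to n, proportional to the weights."""
    total = sum(weights.values())
    shares = {g: n * w / total for g, w in weights.items()}
    counts = {g: int(math.floor(s)) for g, s in shares.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(shares, key=lambda g: (counts[g] + 1 - shares[g], g))
    for g in by_remainder[:leftover]:
        counts[g] += 1
    return counts


def _draw_dims(shape: str, s: float, rng: np.random.Generator) -> dict[str, float]:
    u = rng.uniform
    if shape == "sphere":
        return {"d": s}
    if shape in ("cylinder", "rotational_ellipsoid", "double_cone"):
        return {"d": s, "h": s * u(0.8, 3.0)}
    if shape == "cone_with_half_sphere":
        return {"d": s, "h": s * u(0.6, 2.0)}
    if shape == "tetrahedron":
        return {"a": s, "h": s * u(0.5, 1.5)}
    if shape == "flattened_ellipsoid":
        return {"l": s * u(1.0, 2.0), "w": s * u(0.5, 1.0), "t": s * u(0.2, 0.5)}
    if shape in ("cymbelloid", "oval_cylinder", "parallelepiped",
                 "prism_on_parallelogram_base", "prism_on_triangular_base"):
        return {"l": s * u(1.0, 2.5), "w": s * u(0.4, 1.0), "h": s * u(0.4, 1.0)}
    if shape == "staurastrum":
        return {"d": s, "h": s * u(1.0, 2.0),
                "arm_d": s * u(0.15, 0.3), "arm_l": s * u(0.3, 0.8)}
    if shape == "ceratium":
        return {"l": s * u(1.0, 2.0), "w": s * u(0.5, 1.0), "t": s * u(0.3, 0.6),
                "horn_d": s * u(0.1, 0.2), "horn_l": s * u(0.5, 1.5)}
    raise ValueError(f"no dimension model for shape {shape!r}")


def _bern(rng, p) -> int:
    return int(rng.random() < p)


def _pigments(group: str, rng: np.random.Generator) -> dict[str, int]:
    # start from free defaults, then pin the entries the pigment matrix fixes
    out = {"Chlorophyll_B": 0, "Chlorophyll_C": 0, "Xanthophyll": 0, "Phycobilin": 0}
    if group in ("diatoms", "chrysophytes", "xanthophytes", "dinophytes",
                 "haptophytes", "euglenophytes"):
        out["Xanthophyll"] = 1
    for pigment, value in DEFAULT_PIGMENT_MATRIX.get(group, {}).items():
        out[pigment] = value
    return out


def generate_table(config: SynthConfig | None = None, **kwargs) -> TraitTable:
    """Generate a schema-valid trait table; deterministic for a fixed seed.

    Keyword arguments are a shorthand for :class:`SynthConfig` fields,
    e.g. ``generate_table(n_taxa=50, seed=1)``.
    """
    if config is None:
        config = SynthConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SynthConfig or keyword fields, not both")
    rng = np.random.default_rng(config.seed)
    schema = default_schema()
    quotas = _largest_remainder(config.n_taxa, config.group_weights)

    lf_names = list(config.life_form_weights)
    lf_w = np.asarray([config.life_form_weights[k] for k in lf_names], dtype=float)
    lf_w = lf_w / lf_w.sum()

    rows: list[dict] = []
    used_codes: set[str] = set()
    for group in GROUPS:
        for _ in range(quotas.get(group, 0)):
            rows.append(_draw_record(group, rng, config, lf_names, lf_w, used_codes))
    # one deterministic shuffle so groups are interleaved like a real list
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    df = pd.DataFrame(rows, columns=list(schema.columns))
    for tdef in schema.identity + schema.traits:
        if tdef.kind == "continuous":
            df[tdef.name] = pd.to_numeric(df[tdef.name], errors="coerce").astype(float)
        elif tdef.kind == "boolean":
            df[tdef.name] = pd.array(
                [pd.NA if v is None else int(v) for v in df[tdef.name]], dtype="Int64")
        else:
            df[tdef.name] = pd.array(
                [pd.NA if v is None else str(v) for v in df[tdef.name]], dtype=object)
    table = derive.derive_traits(TraitTable(df, schema))
    for rule_id, count in config.violations:
        for j in range(count):
            table = inject_violation(table, rule_id, seed=int(rng.integers(2 ** 31)))
    return table


def _draw_record(group, rng, config, lf_names, lf_w, used_codes) -> dict:
    """Draw one taxon row whose traits satisfy the cross-checks R1-R15."""
    tax = _TAXONOMY[group]
    # unique (genus, epithet) pair via the 6-letter code
    for _ in range(200):
        genus, family = tax["genera"][rng.integers(len(tax["genera"]))]
        epithet = _EPITHETS[rng.integers(len(_EPITHETS))]
        code = make_taxa_code(genus, epithet)
        if code not in used_codes:
            break
    else:  # pragma: no cover - pools are large enough in practice
        raise RuntimeError("could not find an unused taxa code")
    used_codes.add(code)

    desmid = family in ("Desmidiaceae", "Closteriaceae")
    shapes = _DESMID_SHAPES if desmid else _SHAPE_POOLS[group]
    shape = shapes[rng.integers(len(shapes))]
    lo, hi = config.size_ranges.get(group, (1.0, 100.0))
    base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    dims = _draw_dims(shape, base, rng)
    cell_bv = geometry.cell_biovolume(shape, dims)

    life_form = lf_names[int(rng.choice(len(lf_names), p=lf_w))]
    second_lf = None
    if rng.random() < 0.3:
        others = [f for f in ("cell", "colony", "filament") if f != life_form]
        second_lf = others[rng.integers(len(others))]
    cells = None
    if life_form != "cell":
        cells = float(rng.integers(4, 65))

    dim_values = sorted(dims.values(), reverse=True)
    length = dim_values[0]
    width = dim_values[len(dim_values) // 2]
    thickness = dim_values[-1]
    if life_form == "cell":
        ind_length = length
    elif life_form == "colony":
        ind_length = length * cells ** (1 / 3) * 1.5
    else:  # filament: cells end to end
        ind_length = length * cells

    # group-conditional qualitative traits (satisfy R1-R15 by construction)
    if group in ("diatoms", "cyanobacteria") or desmid:
        flagellum = 0
    elif group in ("cryptophytes", "chrysophytes", "dinophytes",
                   "euglenophytes", "haptophytes"):
        flagellum = 1
    elif group == "chlorophytes":
        flagellum = _bern(rng, 0.4)
    else:
        flagellum = _bern(rng, 0.3)
    flagella_number = float((1, 2, 2, 2, 4, 8)[rng.integers(6)]) if flagellum else None

    plast = 0 if group == "cyanobacteria" else 1
    plastid_number = float(rng.integers(1, 9)) if plast else None
    aerotope = _bern(rng, 0.4) if group == "cyanobacteria" else 0
    if group in ("chrysophytes", "euglenophytes", "cryptophytes"):
        vacuole = 1
    elif group == "chlorophytes":
        vacuole = _bern(rng, 0.3)
    else:
        vacuole = 0
    motility = 1 if (aerotope or vacuole or flagellum) else 0

    protuberance = _bern(rng, 0.25)
    if protuberance:
        p_type = ("granule", "needle", "bristle", "spine", "horn", "wart",
                  "wing")[rng.integers(7)]
        p_size = ("small", "large")[rng.integers(2)]
        p_number = float(rng.integers(1, 9))
    else:
        p_type, p_size, p_number = "None", "None", 0.0

    toxin = _bern(rng, 0.4) if group == "cyanobacteria" else 0
    toxin_family = TOXIN_FAMILIES[rng.integers(len(TOXIN_FAMILIES))] if toxin else None

    if group in ("chrysophytes", "dinophytes", "euglenophytes"):
        nutrition = ("autotroph", "mixotroph", "heterotroph")[
            int(rng.choice(3, p=(0.5, 0.4, 0.1)))]
    else:
        nutrition = ("autotroph", "mixotroph")[int(rng.choice(2, p=(0.9, 0.1)))]

    row = {
        "Taxa_Name": f"{genus} {epithet}",
        "Taxa_Code": code,
        "Group": group,
        "Phylum": tax["phylum"],
        "Class": tax["class"],
        "Order": tax["order"],
        "Family": family,
        "Genus": genus,
        "Species": epithet,
        "Infra_Species": None,
        "Life_Form": life_form,
        "Second_Life_Form": second_lf,
        "Cell_Form": shape,
        "Individual_Form": shape if life_form == "cell"
        else ("sphere" if life_form == "colony" else "cylinder"),
        "Min_Cell_Length": round(length * 0.85, 3),
        "Max_Cell_Length": round(length * 1.15, 3),
        "Min_Cell_Width": round(width * 0.85, 3),
        "Max_Cell_Width": round(width * 1.15, 3),
        "Min_Cell_Thickness": round(thickness * 0.85, 3),
        "Max_Cell_Thickness": round(thickness * 1.15, 3),
        "Min_Individual_Length": round(ind_length * 0.85, 3),
        "Max_Individual_Length": round(ind_length * 1.15, 3),
        "Cells_Per_Individual": cells,
        "Cell_Biovolume": round(cell_bv, 3),
        # derived columns are filled by derive_traits
        "Individual_Biovolume": None,
        "Carbon_Content": None,
        "Sieburth_Class_Min_Length": None,
        "Sieburth_Class_Max_Length": None,
        "Ignatiades_Class": None,
        "Motility": motility,
        "Flagellum": flagellum,
        "Aerotope": aerotope,
        "Contractile_Vacuole": vacuole,
        "Mucilage": _bern(rng, 0.3),
        "Akinete": _bern(rng, 0.35) if group == "cyanobacteria" else 0,
        "Heterocyte": _bern(rng, 0.35) if group == "cyanobacteria" else 0,
        "Cyst": 1 if group in ("chrysophytes", "dinophytes") else _bern(rng, 0.2),
        "Plast": plast,
        "Sheath": _bern(rng, 0.5) if group == "cyanobacteria" else _bern(rng, 0.05),
        "Tractus": _bern(rng, 0.5) if group == "euglenophytes" else _bern(rng, 0.05),
        "Siliceous_Skeleton": 1 if group == "diatoms" else 0,
        "Lorica": _bern(rng, 0.4) if group == "chrysophytes" else 0,
        "External_Plate": _bern(rng, 0.6) if group == "dinophytes" else 0,
        "Scale": 1 if group == "haptophytes"
        else (_bern(rng, 0.5) if group == "chrysophytes" else _bern(rng, 0.1)),
        "Ornamentation": _bern(rng, 0.3),
        "Protuberance": protuberance,
        "Protuberance_Type": p_type,
        "Protuberance_Size": p_size,
        "Protuberance_Number": p_number,
        "Toxin": toxin,
        "Toxin_Family": toxin_family,
        "Flagella_Number": flagella_number,
        "Plastid_Number": plastid_number,
        "Nutrition_Mode": nutrition,
        "Reproduction_Mode": _REPRODUCTION[rng.integers(len(_REPRODUCTION))],
        "Water_Type": ("freshwater", "freshwater-marine", "marine")[
            int(rng.choice(3, p=(0.8, 0.15, 0.05)))],
        "Water_Trophy": _WATER_TROPHY[rng.integers(len(_WATER_TROPHY))],
        "Tolerance": _TOLERANCE[rng.integers(len(_TOLERANCE))]
        if rng.random() < 0.7 else None,
        "Reynolds_Group": _REYNOLDS[rng.integers(len(_REYNOLDS))],
    }
    pig = _pigments(group, rng)
    row.update(pig)
    return row


# ---------------------------------------------------------------------------
# Surgical violation injection
# ---------------------------------------------------------------------------

def _eligible_r3(df, i):
    desmid = df.at[i, "Family"] in ("Desmidiaceae", "Closteriaceae",
                                    "Gonatozygaceae", "Peniaceae", "Mesotaeniaceae")
    in_scope = df.at[i, "Group"] in ("diatoms", "cyanobacteria") or (
        df.at[i, "Group"] == "chlorophytes" and desmid)
    return in_scope and df.at[i, "Flagellum"] == 0


def _mutate_r15(df, i):
    if df.at[i, "Toxin"] == 1:
        df.at[i, "Toxin_Family"] = pd.NA
    else:
        df.at[i, "Toxin_Family"] = "microcystin"


def _truthy(value) -> bool:
    return False if value is pd.NA else bool(value)


#: rule id -> row eligibility predicate for the injection
_INJECTORS: dict[str, object] = {
    "R1": lambda df, i: df.at[i, "Motility"] == 1 and (
        df.at[i, "Aerotope"] == 1 or df.at[i, "Contractile_Vacuole"] == 1
        or df.at[i, "Flagellum"] == 1),
    "R2": lambda df, i: df.at[i, "Flagellum"] == 1,
    "R3": _eligible_r3,
    "R4": lambda df, i: df.at[i, "Group"] == "cryptophytes"
    and df.at[i, "Flagellum"] == 1,
    "R5": lambda df, i: df.at[i, "Plast"] == 1,
    "R6": lambda df, i: df.at[i, "Group"] == "cyanobacteria",
    "R7": lambda df, i: df.at[i, "Group"] != "cyanobacteria"
    and df.at[i, "Heterocyte"] == 0,
    "R8": lambda df, i: df.at[i, "Group"] in ("chrysophytes", "dinophytes")
    and df.at[i, "Cyst"] == 1,
    "R9": lambda df, i: df.at[i, "Group"] != "diatoms"
    and df.at[i, "Siliceous_Skeleton"] == 0,
    "R10": lambda df, i: df.at[i, "Group"] != "dinophytes"
    and df.at[i, "External_Plate"] == 0,
    "R11": lambda df, i: df.at[i, "Group"] not in (
        "chrysophytes", "chlorophytes", "euglenophytes")
    and df.at[i, "Lorica"] == 0,
    "R12": lambda df, i: df.at[i, "Protuberance"] == 1,
    "R13": lambda df, i: df.at[i, "Group"] == "chlorophytes"
    and df.at[i, "Chlorophyll_C"] == 0,
    "R14": lambda df, i: df.at[i, "Group"] != "cyanobacteria"
    and df.at[i, "Toxin"] == 0,
    "R15": lambda df, i: df.at[i, "Group"] == "cyanobacteria",
}


def _apply_mutation(df: pd.DataFrame, i: int, rule_id: str) -> None:
    if rule_id == "R1":
        df.at[i, "Motility"] = 0
    elif rule_id == "R2":
        df.at[i, "Flagella_Number"] = np.nan
    elif rule_id == "R3":
        df.at[i, "Flagellum"] = 1
        df.at[i, "Flagella_Number"] = 2.0
        df.at[i, "Motility"] = 1
    elif rule_id == "R4":
        df.at[i, "Flagellum"] = 0
        df.at[i, "Flagella_Number"] = np.nan
    elif rule_id == "R5":
        df.at[i, "Plastid_Number"] = np.nan
    elif rule_id == "R6":
        df.at[i, "Plast"] = 1
        df.at[i, "Plastid_Number"] = 2.0
    elif rule_id == "R7":
        df.at[i, "Heterocyte"] = 1
    elif rule_id == "R8":
        df.at[i, "Cyst"] = 0
    elif rule_id == "R9":
        df.at[i, "Siliceous_Skeleton"] = 1
    elif rule_id == "R10":
        df.at[i, "External_Plate"] = 1
    elif rule_id == "R11":
        df.at[i, "Lorica"] = 1
    elif rule_id == "R12":
        df.at[i, "Protuberance_Type"] = "None"
    elif rule_id == "R13":
        df.at[i, "Chlorophyll_C"] = 1
    elif rule_id == "R14":
        df.at[i, "Toxin"] = 1
        df.at[i, "Toxin_Family"] = "microcystin"
    elif rule_id == "R15":
        _mutate_r15(df, i)
    else:  # pragma: no cover
        raise KeyError(rule_id)


def inject_violation(table: TraitTable, rule_id: str, seed: int = 0) -> TraitTable:
    """Minimal mutation creating >=1 violation of exactly ``rule_id``.

    One eligible record is chosen reproducibly from ``seed`` and mutated;
    all other records are untouched.  Unknown rule ids and tables without
    an eligible record are errors.
    """
    if rule_id not in _INJECTORS:
        raise KeyError(f"unknown rule id {rule_id!r} (known: R1...R15)")
    eligible_fn = _INJECTORS[rule_id]
    out = table.copy()
    df = out.df
    eligible = [i for i in df.index if _truthy(eligible_fn(df, i))]
    if not eligible:
        raise ValueError(f"no record eligible for an {rule_id} violation")
    rng = np.random.default_rng(seed)
    i = eligible[int(rng.integers(len(eligible)))]
    _apply_mutation(df, i, rule_id)
    return out


def generate_occurrences(
    taxa: Sequence[str],
    n_samples: int,
    prevalence: float | Sequence[float] = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary taxon x sample presence matrix; reproducible for a fixed seed.

    ``prevalence`` is the per-sample presence probability, scalar or one
    value per taxon.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    taxa = [str(t) for t in taxa]
    p = np.broadcast_to(np.asarray(prevalence, dtype=float), (len(taxa),)).copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mat = (rng.random((len(taxa), n_samples)) < p[:, None]).astype(int)
    return pd.DataFrame(
        mat, index=pd.Index(taxa, name="taxon"),
        columns=[f"S{j + 1:04d}" for j in range(n_samples)],
    )
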