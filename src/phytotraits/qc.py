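"""Consistency-rule engine for trait tables.

Fifteen declarative cross-checks (R1-R15) encode the biological coupling
between traits and the nine phytoplankton groups — e.g. motility implied
by aerotopes, contractile vacuoles or flagella; heterocytes and akinetes
restricted to cyanobacteria; a group-wise pigment matrix.  A sixteenth
screen (R16) flags distributional outliers of continuous traits within
each group using Tukey fences.  Rules evaluate per record; a record
missing an input for a rule is skipped for that rule and tallied as
unevaluable, never reported as a violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import TaxonRecord, TraitTable

__all__ = [
    "ValidationRule",
    "Violation",
    "ValidationReport",
    "RULES",
    "TOXIN_FAMILIES",
    "DEFAULT_PIGMENT_MATRIX",
    "DEFAULT_DESMID_FAMILIES",
    "validate_consistency",
    "screen_outliers",
    "summarize_report",
    "is_desmid",
]

#: Closed vocabulary of cyanotoxin families.
TOXIN_FAMILIES = (
    "microcystin",
    "anatoxin-a",
    "anatoxin-a(S)",
    "cylindrospermopsin",
    "saxitoxin",
    "Beta-Methylamino-L-Alanin",
)

#: Families of conjugating green algae treated as desmids (configurable).
DEFAULT_DESMID_FAMILIES = (
    "Desmidiaceae",
    "Closteriaceae",
    "Gonatozygaceae",
    "Peniaceae",
    "Mesotaeniaceae",
)

#: Required pigment states per group.  Only the chlorophyte row is fixed by
#: the original cross-check wording; the other rows are standard pigment
#: systematics shipped as replaceable data.  Unlisted pigments are free.
DEFAULT_PIGMENT_MATRIX: dict[str, dict[str, int]] = {
    "chlorophytes": {"Chlorophyll_B": 1, "Xanthophyll": 1,
                     "Chlorophyll_C": 0, "Phycobilin": 0},
    "cyanobacteria": {"Phycobilin": 1, "Chlorophyll_B": 0, "Chlorophyll_C": 0},
    "diatoms": {"Chlorophyll_C": 1, "Chlorophyll_B": 0},
    "chrysophytes": {"Chlorophyll_C": 1, "Chlorophyll_B": 0},
    "xanthophytes": {"Chlorophyll_C": 1, "Chlorophyll_B": 0},
    "dinophytes": {"Chlorophyll_C": 1, "Chlorophyll_B": 0},
    "cryptophytes": {"Chlorophyll_C": 1, "Phycobilin": 1, "Chlorophyll_B": 0},
    "euglenophytes": {"Chlorophyll_B": 1, "Phycobilin": 0},
    "haptophytes": {"Chlorophyll_C": 1, "Chlorophyll_B": 0, "Phycobilin": 0},
}


def is_desmid(record: TaxonRecord,
              families: Sequence[str] = DEFAULT_DESMID_FAMILIES) -> bool:
    """Whether a record belongs to the desmid subset of the chlorophytes."""
    return record.taxonomy.get("family") in set(families)


@dataclass(frozen=True)
class Violation:
    taxon_name: str
    rule_id: str
    severity: str  # "error" | "warning"
    message: str
    offending: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ValidationRule:
    """One consistency cross-check applied record by record.

    ``check`` returns a list of (severity, message, offending) findings,
    an empty list for a pass, or None when the record's inputs are too
    incomplete to evaluate.
    """

    id: str
    description: str
    severity: str
    check: Callable[[TaxonRecord], list[tuple[str, str, dict]] | None]


# -- rule helpers -----------------------------------------------------------

_UNEVALUABLE = None


def _r1(rec: TaxonRecord):
    indicators = {t: rec.trait(t) for t in ("Aerotope", "Contractile_Vacuole", "Flagellum")}
    present = [t for t, v in indicators.items() if v == 1]
    if not present:
        return [] if None not in indicators.values() else _UNEVALUABLE
    mot = rec.trait("Motility")
    if mot is None:
        return _UNEVALUABLE
    if mot != 1:
        return [("error", f"motility must be 1 when {', '.join(present)} present",
                 {"Motility": mot, **{t: 1 for t in present}})]
    return []


def _r2(rec: TaxonRecord):
    fla = rec.trait("Flagellum")
    if fla is None:
        return _UNEVALUABLE
    num = rec.trait("Flagella_Number")
    if fla == 1 and (num is None or num <= 0):
        return [("error", "flagella number must be given with presence of flagellum",
                 {"Flagellum": 1, "Flagella_Number": num})]
    if fla == 0 and num is not None and num > 0:
        return [("error", "flagella number given although flagellum is absent",
                 {"Flagellum": 0, "Flagella_Number": num})]
    return []


def _r3(rec: TaxonRecord):
    if rec.group not in ("diatoms", "cyanobacteria") and not (
        rec.group == "chlorophytes" and is_desmid(rec)
    ):
        return []
    fla = rec.trait("Flagellum")
    if fla is None:
        return _UNEVALUABLE
    if fla == 1:
        kind = "desmid" if rec.group == "chlorophytes" else rec.group
        return [("error", f"flagellum must be absent for {kind} taxa",
                 {"Flagellum": 1, "Group": rec.group})]
    return []


def _r4(rec: TaxonRecord):
    if rec.group != "cryptophytes":
        return []
    fla = rec.trait("Flagellum")
    if fla is None:
        return _UNEVALUABLE
    if fla != 1:
        return [("error", "flagellum is compulsory for cryptophytes",
                 {"Flagellum": fla})]
    return []


def _r5(rec: TaxonRecord):
    pl = rec.trait("Plast")
    if pl is None:
        return _UNEVALUABLE
    num = rec.trait("Plastid_Number")
    if pl == 1 and (num is None or num <= 0):
        return [("error", "plastid number must be given with presence of plastids",
                 {"Plast": 1, "Plastid_Number": num})]
    if pl == 0 and num is not None and num > 0:
        return [("error", "plastid number given although plastids are absent",
                 {"Plast": 0, "Plastid_Number": num})]
    return []


def _r6(rec: TaxonRecord):
    if rec.group != "cyanobacteria":
        return []
    pl = rec.trait("Plast")
    if pl is None:
        return _UNEVALUABLE
    if pl == 1:
        return [("error", "plastids must be absent for cyanobacteria taxa",
                 {"Plast": 1})]
    return []


def _r7(rec: TaxonRecord):
    aki, het = rec.trait("Akinete"), rec.trait("Heterocyte")
    if aki is None and het is None:
        return _UNEVALUABLE
    findings = []
    if rec.group != "cyanobacteria":
        for t, v in (("Akinete", aki), ("Heterocyte", het)):
            if v == 1:
                findings.append(
                    ("error", f"{t.lower()} occurs only in cyanobacteria",
                     {t: 1, "Group": rec.group})
                )
    return findings


def _r8(rec: TaxonRecord):
    if rec.group not in ("chrysophytes", "dinophytes"):
        return []
    cyst = rec.trait("Cyst")
    if cyst is None:
        return _UNEVALUABLE
    if cyst != 1:
        return [("error", f"cyst is compulsory for {rec.group} taxa",
                 {"Cyst": cyst})]
    return []


def _only_in_group(trait: str, groups: tuple[str, ...], label: str):
    def check(rec: TaxonRecord):
        v = rec.trait(trait)
        if v is None:
            return _UNEVALUABLE
        if v == 1 and rec.group not in groups:
            return [("error", f"{label} occurs only in {' / '.join(groups)}",
                     {trait: 1, "Group": rec.group})]
        return []

    return check


def _r11(rec: TaxonRecord):
    v = rec.trait("Lorica")
    if v is None:
        return _UNEVALUABLE
    if v != 1 or rec.group == "chrysophytes":
        return []
    if rec.group in ("chlorophytes", "euglenophytes"):
        return [("warning", "lorica occurs in only a few chlorophytes and "
                            "euglenophytes; verify", {"Lorica": 1, "Group": rec.group})]
    return [("error", "lorica occurs only in chrysophytes and a few "
                      "chlorophytes / euglenophytes",
             {"Lorica": 1, "Group": rec.group})]


def _r12(rec: TaxonRecord):
    pres = rec.trait("Protuberance")
    if pres is None:
        return _UNEVALUABLE
    ptype = rec.trait("Protuberance_Type")
    psize = rec.trait("Protuberance_Size")
    pnum = rec.trait("Protuberance_Number")
    offending = {"Protuberance": pres, "Protuberance_Type": ptype,
                 "Protuberance_Size": psize, "Protuberance_Number": pnum}
    if pres == 1:
        if ptype in (None, "None") or psize in (None, "None") or pnum is None or pnum <= 0:
            return [("error", "protuberance present but type/size/number not "
                              "consistently given", offending)]
    else:
        if (ptype not in (None, "None")) or (psize not in (None, "None")) or (
            pnum is not None and pnum > 0
        ):
            return [("error", "protuberance detail given although protuberance "
                              "is absent", offending)]
    return []


def _r13(rec: TaxonRecord, matrix: Mapping[str, Mapping[str, int]] | None = None):
    matrix = matrix or DEFAULT_PIGMENT_MATRIX
    row = matrix.get(rec.group or "")
    if row is None:
        return []
    findings = []
    n_missing = 0
    for pigment, expected in row.items():
        v = rec.trait(pigment)
        if v is None:
            n_missing += 1
        elif v != expected:
            word = "present" if expected else "absent"
            findings.append(
                ("error", f"{pigment} must be {word} for {rec.group}",
                 {pigment: v, "Group": rec.group})
            )
    if not findings and n_missing == len(row):
        return _UNEVALUABLE
    return findings


def _r14(rec: TaxonRecord):
    tox = rec.trait("Toxin")
    if tox is None:
        return _UNEVALUABLE
    if tox == 1 and rec.group != "cyanobacteria":
        return [("error", "potential toxin production occurs only in "
                          "cyanobacteria", {"Toxin": 1, "Group": rec.group})]
    return []


def _r15(rec: TaxonRecord):
    tox = rec.trait("Toxin")
    if tox is None:
        return _UNEVALUABLE
    fam = rec.trait("Toxin_Family")
    if tox == 1 and fam is None:
        return [("error", "toxin family must be given with presence of toxin",
                 {"Toxin": 1, "Toxin_Family": None})]
    if tox == 0 and fam is not None:
        return [("error", "toxin family given although toxin is absent",
                 {"Toxin": 0, "Toxin_Family": fam})]
    return []


RULES: tuple[ValidationRule, ...] = (
    ValidationRule("R1", "motility set to 1 when aerotope, contractile vacuole "
                         "or flagellum are present", "error", _r1),
    ValidationRule("R2", "number of flagella indicated with presence of "
                         "flagellum", "error", _r2),
    ValidationRule("R3", "absence of flagellum for desmids, diatoms and "
                         "cyanobacteria", "error", _r3),
    ValidationRule("R4", "compulsory flagellum for cryptophytes", "error", _r4),
    ValidationRule("R5", "number of plastids indicated with the presence of "
                         "plastids", "error", _r5),
    ValidationRule("R6", "absence of plastids for cyanobacteria taxa", "error", _r6),
    ValidationRule("R7", "presence of akinete and heterocyte only for "
                         "cyanobacteria taxa", "error", _r7),
    ValidationRule("R8", "compulsory cyst for chrysophytes and dinophytes taxa",
                   "error", _r8),
    ValidationRule("R9", "siliceous skeleton only for diatoms", "error",
                   _only_in_group("Siliceous_Skeleton", ("diatoms",),
                                  "siliceous skeleton")),
    ValidationRule("R10", "presence of external plates only for dinophytes",
                   "error",
                   _only_in_group("External_Plate", ("dinophytes",),
                                  "external plates")),
    ValidationRule("R11", "lorica for chrysophytes and few chlorophytes and "
                          "euglenophytes", "error", _r11),
    ValidationRule("R12", "protuberance type other than None and size not null "
                          "with presence of protuberance", "error", _r12),
    ValidationRule("R13", "group-wise pigment matrix (chlorophytes: "
                          "chlorophyll-b and xanthophyll present, "
                          "chlorophyll-c and phycobilin absent; equivalent "
                          "controls for the other groups)", "error", _r13),
    ValidationRule("R14", "presence of toxin only for some cyanobacteria",
                   "error", _r14),
    ValidationRule("R15", "the toxin family indicated with presence of toxin",
                   "error", _r15),
)

RULES_BY_ID: dict[str, ValidationRule] = {r.id: r for r in RULES}


@dataclass
class ValidationReport:
    """Findings of a consistency run over a table."""

    violations: list[Violation]
    n_records_checked: int
    unevaluable: dict[str, int] = field(default_factory=dict)
    skipped_screens: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for v in self.violations if v.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for v in self.violations if v.severity == "warning")

    def counts_by_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.violations:
            counts[v.rule_id] = counts.get(v.rule_id, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon": v.taxon_name,
                    "rule": v.rule_id,
                    "severity": v.severity,
                    "message": v.message,
                    "offending": "; ".join(f"{k}={val}" for k, val in v.offending.items()),
                }
                for v in self.violations
            ],
            columns=["taxon", "rule", "severity", "message", "offending"],
        )


def validate_consistency(
    table: TraitTable,
    rules: Sequence[ValidationRule] = RULES,
) -> ValidationReport:
    """Apply the consistency cross-checks R1-R15 to every record."""
    violations: list[Violation] = []
    unevaluable: dict[str, int] = {r.id: 0 for r in rules}
    for rec in table.records():
        for rule in rules:
            findings = rule.check(rec)
            if findings is None:
                unevaluable[rule.id] += 1
                continue
            for severity, message, offending in findings:
                violations.append(
                    Violation(
                        taxon_name=rec.taxon_name,
                        rule_id=rule.id,
                        severity=severity,
                        message=message,
                        offending=offending,
                    )
                )
    return ValidationReport(
        violations=violations,
        n_records_checked=len(table),
        unevaluable=unevaluable,
    )


def screen_outliers(
    table: TraitTable,
    k: float = 1.5,
    min_group_n: int = 5,
) -> ValidationReport:
    """Tukey-fence outlier screen of continuous traits within each group.

    Values outside [Q1 - k*IQR, Q3 + k*IQR], computed per group and trait,
    are flagged as R16 warnings (never errors).  Group/trait combinations
    with fewer than ``min_group_n`` non-missing values are skipped and
    listed in the report; a zero IQR yields no flags.
    """
    if k <= 0:
        raise ValueError(f"fence multiplier k must be > 0, got {k}")
    schema = table.schema
    continuous = [d.name for d in schema.traits
                  if d.kind == "continuous" and d.name in table.df.columns]
    violations: list[Violation] = []
    skipped: list[tuple[str, str, int]] = []
    df = table.df
    groups = df["Group"] if "Group" in df.columns else pd.Series(["?"] * len(df))
    for group, idx in df.groupby(groups, dropna=False).groups.items():
        sub = df.loc[idx]
        for trait in continuous:
            vals = pd.to_numeric(sub[trait], errors="coerce")
            ok = vals.dropna()
            if len(ok) < min_group_n:
                skipped.append((str(group), trait, int(len(ok))))
                continue
            q1, q3 = np.percentile(ok.to_numpy(float), [25, 75])
            iqr = q3 - q1
            if iqr == 0:
                continue
            lo, hi = q1 - k * iqr, q3 + k * iqr
            out = ok[(ok < lo) | (ok > hi)]
            for row_pos, value in out.items():
                name = str(df.at[row_pos, "Taxa_Name"]) if "Taxa_Name" in df.columns \
                    else f"row {row_pos}"
                violations.append(
                    Violation(
                        taxon_name=name,
                        rule_id="R16",
                        severity="warning",
                        message=f"{trait}={value} outside Tukey fences "
                                f"[{lo:.6g}, {hi:.6g}] for group {group}",
                        offending={trait: value, "Group": group},
                    )
                )
    return ValidationReport(
        violations=violations,
        n_records_checked=len(table),
        skipped_screens=skipped,
    )


def summarize_report(report: ValidationReport) -> tuple[str, pd.DataFrame]:
    """Human-readable summary and a per-rule count table.

    The recommended process exit status is 1 iff the report holds at least
    one error (exposed as ``report.n_errors``).
    """
    counts = report.counts_by_rule()
    frame = pd.DataFrame(
        [
            {
                "rule": rid,
                "violations": n,
                "severity": RULES_BY_ID[rid].severity if rid in RULES_BY_ID else "warning",
            }
            for rid, n in sorted(counts.items())
        ],
        columns=["rule", "violations", "severity"],
    )
    lines = [
        f"{report.n_records_checked} records checked: "
        f"{report.n_errors} errors, {report.n_warnings} warnings"
    ]
    for rid, n in sorted(counts.items()):
        lines.append(f"  {rid}: {n}")
    for rid, n in sorted(report.unevaluable.items()):
        if n:
            lines.append(f"  {rid}: {n} record(s) unevaluable (missing inputs)")
    for group, trait, n in report.skipped_screens:
        lines.append(f"  outlier screen skipped for {trait} in {group} (n={n})")
    return "\n".join(lines), frame
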