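# Methods

This note documents the models, conventions and design choices behind
`phytotraits`, and what the synthetic-data tests do and do not demonstrate
about real trait compilations.

## Data model

A trait table is a taxon × variable matrix in semicolon-separated CSV with
`#NA` marking missing cells (separator, missing token, decimal mark and
encoding are all configurable; the decimal mark matters for tables exported
from French-locale spreadsheets). The packaged schema types 10
identity/taxonomy columns (name, 6-letter code, group, phylum … infra-species)
and exactly 53 trait variables:

* life forms (primary + secondary) and geometric forms (cell + individual): 4
* linear dimensions in µm (min/max cell length, width and thickness;
  min/max individual length): 8, plus cells per individual: 1
* biovolumes (cell, individual) and carbon content: 3
* size classes (Sieburth on min length, Sieburth on max length, Ignatiades): 3
* binary traits (1-presence, 0-absence): motility, flagellum, aerotopes,
  contractile vacuoles, mucilage, akinetes, heterocytes, cysts, plastids,
  sheath, tractus, siliceous skeleton, lorica, external plates, scales,
  ornamentations, protuberances, chlorophyll-b, chlorophyll-c, xanthophyll,
  phycobilin, toxin potential: 22
* flagella and plastid counts: 2; protuberance type/size/number: 3;
  toxin family: 1
* nutrition mode, reproduction mode, water type, water trophy, tolerance,
  Reynolds group: 6

Boolean variables admit exactly {0, 1, missing}; categorical variables carry
closed vocabularies (e.g. the six cyanotoxin families: microcystin,
anatoxin-a, anatoxin-a(S), cylindrospermopsin, saxitoxin,
Beta-Methylamino-L-Alanin). Reynolds functional groups are stored as a
categorical/text trait only — no assignment algorithm is provided or implied.
An alias map in the schema file translates external header spellings to the
canonical names, isolating header drift in deposited files from the code.
Unknown columns pass through untouched so provenance/reference columns
survive a round trip. Writing uses `repr` for floats, which guarantees
read-back-identical values.

The nine groups default to chlorophytes, cyanobacteria, diatoms,
chrysophytes, xanthophytes, dinophytes, euglenophytes, cryptophytes and
haptophytes. The ninth slot is the least standardized in practice; the group
vocabulary lives in the schema file and can be replaced. Desmids are treated
as the subset of chlorophytes whose family is one of Desmidiaceae,
Closteriaceae, Gonatozygaceae, Peniaceae, Mesotaeniaceae (configurable).

## Taxa codes and list cleaning

Codes are 6 uppercase ASCII letters: the first 3 letters of the genus plus 3
letters of the lowest-rank epithet (the infra-specific denomination when
present, otherwise the species epithet), after stripping diacritics and
non-alphabetic characters. The default takes the *first* three letters of
the epithet, which matches the common counting-software style; a `last3`
option covers the alternative reading of "the last 3 letters". Genus-only
determinations (or placeholder epithets such as "sp.") get the filler `SPX`.
Code collisions within a table are reported as errors and resolved only
through an explicit override map — silent mangling would break joins against
external code lists.

Rank cleaning keeps genus and everything below (species, subspecies,
variety, form); order, class and phylum determinations are rejected. The
lowest determined rank is inferred from the taxonomy columns or supplied
explicitly; unknown rank labels are errors.

## Biovolume

Volumes follow the standard simple-solid approach. Closed forms, all in µm³
with dimensions in µm:

| form | dims | volume |
|---|---|---|
| sphere | d | (π/6)·d³ |
| cylinder | d, h | (π/4)·d²·h |
| rotational ellipsoid | d, h | (π/6)·d²·h |
| flattened ellipsoid | l, w, t | (π/6)·l·w·t |
| cymbelloid | l, w, h | (π/8)·l·w·h |
| oval cylinder | l, w, h | (π/4)·l·w·h |
| double cone | d, h | (π/12)·d²·h |
| parallelepiped | l, w, h | l·w·h |
| prism on parallelogram base | l, w, h | (1/2)·l·w·h |
| prism on triangular base | l, w, h | (1/2)·l·w·h |
| cone with half sphere | d, h (total, ≥ d/2) | (π/12)·d²·(h + d/2) |
| tetrahedron | a, h | (√3/12)·a²·h |
| ceratium form | l, w, t, horn_d, horn_l (+ n_horns) | (π/6)·l·w·t + n·(π/12)·horn_d²·horn_l |
| staurastrum form | d, h, arm_d, arm_l (+ n_arms) | (π/12)·d²·h + n·(π/12)·arm_d²·arm_l |

Design choices worth noting:

* The **cymbelloid** is modelled as a half elliptic cylinder; the
  **prism on parallelogram base** as a prism over a rhombus with diagonals
  w and h (hence the same (1/2)·l·w·h as the triangular prism); the
  **tetrahedron** as a pyramid over an equilateral triangle of edge a with
  apex height h. These are declared decompositions, replaceable if a
  different counting-tool convention is needed.
* **Ceratium** and **staurastrum** forms are composite: a body (flattened
  ellipsoid / double cone) plus k appendage cones. k defaults to 3 horns and
  4 arms respectively and is an integer parameter, deliberately kept outside
  the dimension set so that every volume is homogeneous of degree 3 in its
  dimensions (scaling all lengths by c scales volume by c³ — a property
  test over all 14 forms).
* Every formula is checked against an in-package **hit-or-miss Monte-Carlo
  oracle**: each shape declares bounding boxes and membership predicates for
  its component solids; composite components are sampled in disjoint boxes
  stacked along one axis (volumes are additive), giving an unbiased estimate
  with standard error box_volume·√(p(1−p)/n). The verification suite runs
  100 random dimension sets per shape at n = 10⁶ and requires agreement
  within max(1 %, 3 SE).

Individual (natural-unit) biovolume is the cell biovolume for unicellular
taxa and cell biovolume × cells-per-individual for colonies and filaments —
a deliberately simple multiplicative model; mucilage and packing geometry
are ignored. A missing cell count yields a missing individual biovolume plus
a provenance flag rather than an error.

## Carbon and size classes

Carbon per cell uses the allometric models C = 0.216·V^0.939 (general) and
C = 0.288·V^0.811 (diatoms), V being the *mean cell* biovolume in µm³ and C
in pg. The curves cross at V = (0.288/0.216)^(1/0.128) ≈ 9.46 µm³; the test
suite asserts the sign change around that point.

All class intervals are **left-closed right-open**: printed range
definitions overlap at their endpoints ("2–20" / "20–200 µm"), so one
convention has to be chosen; left-closed makes 20 µm microphytoplankton and
10⁶ µm³ macroplankton, and is applied uniformly. Sieburth classes are
computed twice, from the minimum and the maximum individual length; lengths
outside 0.2 µm – 20 mm clamp to the end classes with a flag (trait
compilations contain extremes, and data should survive with provenance
rather than be rejected). The Ignatiades class is computed on the individual
biovolume; when that is missing (colonial taxon without a cell count) it
falls back to the cell biovolume, again with a flag.

`derive_traits` applies all of this row-wise, overwrites only the five
derived columns, records flags, and is idempotent.

## Occurrence filter

A taxon is kept iff it occurs in **strictly more than** `min_samples`
(default 15) samples of a binary occurrence matrix — with the default, 15
occurrences drop a taxon and 16 keep it. Because the strictness of the
published wording is not verifiable from the data alone, both the threshold
and the strict/non-strict semantics are keyword arguments.

## Consistency rules

R1–R15 encode trait–trait and trait–group couplings; R16 is distributional.

| id | check | severity |
|---|---|---|
| R1 | motility = 1 whenever aerotope, contractile vacuole or flagellum present | error |
| R2 | flagella count present (and > 0) iff flagellum present | error |
| R3 | no flagellum in desmids, diatoms, cyanobacteria | error |
| R4 | flagellum compulsory in cryptophytes | error |
| R5 | plastid count present iff plastids present | error |
| R6 | no plastids in cyanobacteria | error |
| R7 | akinetes/heterocytes only in cyanobacteria | error |
| R8 | cyst compulsory in chrysophytes and dinophytes | error |
| R9 | siliceous skeleton only in diatoms | error |
| R10 | external plates only in dinophytes | error |
| R11 | lorica: silent in chrysophytes, warning in chlorophytes/euglenophytes (rare but real), error elsewhere | mixed |
| R12 | protuberance presence ⇔ type ≠ "None" ∧ size set ∧ number > 0 | error |
| R13 | group pigment matrix (chlorophytes: chl-b and xanthophyll present, chl-c and phycobilin absent; cyanobacteria: phycobilin only; diatoms/chrysophytes/xanthophytes/dinophytes: chl-c, no chl-b; cryptophytes: chl-c + phycobilin; euglenophytes: chl-b, no phycobilin; haptophytes: chl-c) | error |
| R14 | toxin potential only in cyanobacteria | error |
| R15 | toxin family present ⇔ toxin = 1 | error |
| R16 | Tukey fences (k = 1.5) per group × continuous trait | warning |

Rules R1, R7, R9, R10, R14 are one-directional implications; R2, R5, R12,
R15 are biconditionals. Only the chlorophyte pigment row is dictated by the
original cross-check wording; the other rows follow standard pigment
systematics and ship as replaceable data, as do the desmid family list and
severity assignments (the intended fatal-vs-advisory split is not published;
the defaults here are declared, not inferred). A record missing an input for
a rule is tallied as *unevaluable* for that rule — missingness is data,
never an error. The R16 screen needs at least 5 non-missing values per
group × trait, skips (and reports) smaller cells, and treats a zero IQR as
no-flag; it is a screen for humans, so it only ever warns. Fences are
applied on the raw scale; heavily skewed traits such as biovolume can
legitimately trip it, which is another reason R16 never errors.

## Synthetic generator

The generator emulates the *structure* of a compiled national trait table:
nine groups with largest-remainder quota allocation (exact compositions, so
tests can assert counts deterministically; default weights give a
chlorophyte-dominated list of roughly 36.5 % chlorophytes down to 2.2 %
cryptophytes), cell/colony/filament life forms (≈ 57/33/10 % by default),
group-typical geometric forms with log-uniform base sizes per group
(0.8–200 µm across groups, chosen so that all Sieburth and Ignatiades
classes occur at moderate n), and group-conditional qualitative traits drawn
to satisfy R1–R15 by construction. Cell biovolume is computed from the drawn
shape and dimensions through the geometry module, and all derived columns
through `derive_traits`, so generated tables are a fixed point of the
derivation and validate clean.

`inject_violation` applies a minimal mutation to one eligible record so that
exactly the requested rule fails — co-dependent traits are co-mutated to
avoid collateral findings (e.g. making a diatom flagellate for R3 also sets
its flagella count and motility so R1/R2 stay green). This gives the rule
engine a per-rule sensitivity test with a known ground truth.

What the generator does **not** emulate: real covariance between size and
ecology, realistic taxonomies beyond small genus pools, measurement noise in
dimensions, structured missingness, or the actual French lake flora. Green
tests therefore demonstrate correctness of the computations and the rule
logic, not fitness of any particular real compilation.

## Numerical and interface choices

* Composition percentages are rounded half-up to one decimal (display
  convention of published composition figures); raw counts are always
  carried alongside.
* Monte-Carlo estimates are reproducible for a fixed seed
  (`numpy.random.default_rng`); the minimum sample count is 10⁴.
* CSV round-trip identity (write → read reproduces the table exactly,
  including missing cells, dtypes and column order) is a tested invariant,
  on both the default dialect and a comma-decimal variant.
* The CLI is a thin click layer; exit status 0 = clean, 1 = validation
  errors found, 2 = usage/IO errors.
* Problem sizes in the verification suite: rule-engine soundness on 20
  generator seeds at n = 200; Monte-Carlo formula verification at 100
  dimension sets × 10⁶ samples per shape; round-trip identity on 1 000
  independently drawn small tables.

## Known limitations

* The composite-form decompositions (ceratium, staurastrum, cymbelloid) are
  this package's declared conventions; other counting tools may parameterize
  these solids differently, and biovolumes for those forms are comparable
  across datasets only under the same convention.
* Surface area, sinking velocity, shape plasticity and per-sample
  measurement workflows are out of scope.
* No taxonomy services: synonymy must be resolved upstream; the code/rank
  utilities operate on whatever names the table carries.
* The pigment matrix and severity assignments beyond the documented
  chlorophyte row are defaults, intended to be overridden where a
  compilation follows different conventions.
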