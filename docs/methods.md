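# Methods

This note documents the curation model implemented by `drugcure`: the
identity rules, the hierarchy and aggregation semantics, each rule-based
classifier with its parameters and defaults, the trial-mapping procedure,
what the synthetic fixtures emulate, and the numerical/design choices made
where the design was genuinely open.

## Compound identity

A compound's identity is its **full 27-character standard InChIKey**
computed from the standardized structure (RDKit cleanup +
functional-group normalization; InChI from the sanitized molecule). Using
the full key — not the 14-character connectivity block — means that
stereoisomers, isotopologues and salts are distinct compounds; their
relationship is expressed through the hierarchy, never by merging.
Biotherapeutics without structures are identified by exact normalized
name only: lowercase, trimmed, whitespace-collapsed, Greek letters written
out (α → alpha). Fuzzy name similarity is deliberately excluded from
automatic merging; anything non-exact lands in a review queue, because
different biologic generations and manufacturing processes can share
near-identical names while being distinct substances.

The structure checker is a pluggable contract. The built-in scorer marks
valence violations and kekulization failures with penalty 6 and other
sanitization warnings with penalty 2; the inclusion threshold is **5**, so
a valence-broken structure is kept but routed to manual review rather than
silently dropped or auto-fixed. The threshold and the failure taxonomy are
deliberately coarse — the checker exists to gate review, not to grade
chemistry.

## Hierarchy and aggregation

Parent derivation removes fragments found in the **salt/solvent
dictionary** (`data/salt_fragments.tsv`, ~30 entries, matched at
charge-normalized connectivity level), clears isotopes to natural
abundance, and neutralizes trivially protonatable/deprotonatable charges
(RDKit Uncharger). Tautomer canonicalization is **not** attempted:
neutralization can land on a non-preferred tautomer, and those cases are
handled exclusively through manually fixed hierarchy links, which always
override automatic derivation. If a stripped parent structure is not
registered, a *virtual parent* entry is created carrying no provenance
rows — it exists only to anchor the family.

Aggregation onto the parent: `max_phase` maximum under the order
4 > 3 > 2 > 1 > 0.5 > −1 with NULL ignored (−1, "unknown", sits above NULL
because it still marks a curated drug form); route/therapeutic/withdrawn/
warning/inorganic/polymer booleans OR upward; `first_approval` and
`usan_year` take the minimum year; chirality copies to the parent only
when uniform across annotated members — disagreement is reported, not
resolved. `dosed_ingredient` never aggregates: it is the one flag that
distinguishes whether the parent form itself is administered. The
`prodrug` flag propagates to every family member curated as a drug or
clinical candidate (`max_phase` not NULL); research-only members are left
untouched. The schema permits exactly one active ingredient per prodrug;
a second distinct active raises a constraint error rather than guessing.

## Classifier rules and parameters

**max_phase** (4 / 3 / 2 / 1 / 0.5 / −1 / NULL). Category 4 requires a
human-use regulatory source: an approved-products or new-approvals feed, a
withdrawn-drugs source (withdrawal presupposes approval), or an EMA source
backed by a human-use approval event. An ATC source gives 4 only when no
other regulatory source exists anywhere in the family — the ATC list
enumerates marketed ingredients but is not itself a regulator, so it
yields when real regulatory evidence is present. Name applications carry
phase information by convention: INN applications are filed around Phase 2
and count as phase-2 evidence; USAN applications around Phase 1–2 and
count as phase-1 evidence. Trial phases contribute their own level, Early
Phase 1 contributing 0.5. A **Phase 4 trial alone contributes 3 plus a
review flag**: a trial registry's phase label cannot certify regulatory
approval (design choice; the alternative of assigning −1 would discard
real late-stage evidence). A drug source with no phase evidence at all —
e.g. a veterinary-only EMA record — resolves to −1; no drug source and no
trials resolves to NULL (research compound). The resolution is a max over
a set, hence invariant to evidence order.

**Chirality.** Structureless biotherapeutic → 1 (biological building
blocks have defined configuration). No potential stereocenters → 2.
Stereocenters present and stereo drawn: if the standard InChI of the
molecule equals that of its mirror image (every tetrahedral tag inverted
in the isomeric SMILES), the molecule is superimposable on its mirror
image — meso/internal symmetry — and classified 2; otherwise fully
assigned centers give 1. Stereocenters present but stereo absent or
partial → 0 (a mixture of unspecified proportion). The mirror test is
only applied when stereo is drawn: without a stereo layer it is trivially
true and uninformative. Name patterns (±, RS, D/L) annotate a review note
and never decide the category.

**Availability type.** −2 (withdrawn) requires the withdrawn flag plus
either a discontinued marketing status (approved-products feed) or an
uncurated status (other feeds); a drug still marketed in one region keeps
its marketing code (2 OTC / 1 Rx / 0 discontinued) even when withdrawn
elsewhere. Non-approved-products drugs default to −1 (status not
curated); research compounds to NULL. The function is total over its
input cross-product.

**Withdrawal.** Eligible iff some event withdraws all doses, all
populations, and all indications on a safety basis (including
safety-related drug–drug interactions). A "suspended" status is
equivocal — it qualifies only when corroborated by additional references.
Efficacy-only withdrawals never qualify. The warning year is the earliest
qualifying year; it does not reset `first_approval`, which remains the
earliest human-use approval across withdrawal/reapproval cycles.

**Other rules.** Preferred names: regulator's name for approved drugs,
else USAN > INN > fallback dictionary name, Greek letters spelled out.
Molecule type: name-suffix table (−mab antibody, −ase enzyme, …,
`data/type_suffixes.tsv`) plus SMARTS substructure rules for structured
biologics; conflicting evidence yields "unknown" + review; structured
compounds default to "small molecule". The inorganic flag is the literal
element-set rule (no atom in {H,C,N,O,P,S,F,Cl,Br,I}); note the known
limitation that it classifies simple halide salts such as NaCl as organic
because they contain a listed halogen — implemented as specified, flagged
here. USAN stems (`data/usan_stems.tsv`, prefix/infix/suffix): longest
matching stem wins. `usan_year > first_approval` emits a warning only
(a name application should precede approval). `first_in_class`, `orphan`,
`veterinary`, route booleans and `black_box_warning` are pass-through
annotations: their upstream assignment is manual or model-driven and out
of scope, so the engine stores and aggregates them without automation.

## Ontology similarity

The disease ontology is a DAG of `is_a` relations loaded from OBO text
(obonet); cycles, dangling references, and obsolete terms without a
replacement are load errors. Information content uses the
descendant-count corpus: IC(t) = −ln((|descendants(t)|+1)/N) with N the
number of non-obsolete terms — no external annotation corpus is needed,
and a root covering everything has IC 0. Pairwise similarity is the
**Lin measure**, 2·IC(MICA)/(IC(a)+IC(b)); identical terms score 1, terms
sharing only a zero-IC root score 0. The measure is a pluggable choice;
Lin is the default because it is normalized to [0,1], symmetric, and
directly compatible with the fixed 0.85 disentanglement threshold. The
threshold applies to whichever measure is configured.

## Trial mapping

Filtering keeps interventional studies with an exact phase (never "not
applicable") updated within the extraction window. Mapping is three-stage
and conservative: (1) curated-dictionary hit on the normalized string,
skipped when the entry is marked not-for-automatic-mapping; (2) exact
match against a preferred name or synonym; (3) otherwise **no automatic
assignment** — every dictionary name of length ≥ 4, not blocklisted, that
occurs as a substring of the lowercased, punctuation-stripped text is
returned as a review candidate. The < 4-character exclusion removes
acronyms that substring-match everywhere; the blocklist removes known
traps (a short synonym of one drug occurring inside another drug's name,
a broad disease term inside a more specific condition string). Word
boundaries are deliberately not required, mirroring how such traps arise
in practice.

Single-condition trials confirm the condition for every mapped drug.
Multi-condition trials are confirmed wholesale only when **all pairwise
similarities reach 0.85**; otherwise the trial enters a manual queue and
is excluded from output until reviewed. Within a trial, a mapped term is
redundant iff another mapped term is its strict descendant; at least one
term always survives. Indication rows carry `max_phase_for_ind` from the
trial phase (Early Phase 1 → 0.5 … Phase 3 → 3); Phase 4 rows are kept
only when the (drug, condition) pair holds regulatory approval, keyed on
(molregno, ontology term id) as supplied by the caller. Ontology terms
translate to MeSH descriptors; pairs with no equivalent are dropped.
Duplicate pairs collapse to the maximum phase, accumulating trial ids as
references. Indication text maps only into MeSH branches C, E, F plus an
explicit allowlist (e.g. a G13 term), never to supplementary concept
records; among tree-related candidates only the most specific survives,
and unrelated equally-specific candidates are all kept.

## Synthetic fixtures

The generator produces every input the pipeline consumes: compound
families (parent scaffolds from a fixed SMILES list, salts built by
attaching counterions, ~20 % structureless biotherapeutics, ~17 %
research-only entries), a ClinicalTrials.gov-v2-style JSON feed mixing
exact/partial/placebo/non-specific/absent interventions and
single/multi/nested-condition trials across all phases, a 16-term disease
ontology, a MeSH-like vocabulary, and dictionaries/blocklists. All
randomness is seeded (`random.Random(seed)`); regeneration is
byte-identical. A separate bundle reconstructs the worked curation
scenarios — approved-salt aggregation, three-form prodrug propagation,
the 1963/1973/1997/2020 approval-withdrawal-reapproval sequence, the
four-condition redundancy case, meso chirality, withdrawal eligibility,
and the availability codes — with expected outcomes in a manifest that a
full pipeline run must reproduce exactly.

What the fixtures do **not** emulate: real compound structures (scaffolds
are stand-ins; the tests assert rule behavior, not chemistry), realistic
corpus scale, the breadth of a real disease ontology, or the noisiness of
free-text trial records. Passing tests therefore demonstrate that the
rules and plumbing behave as specified, not that real-world mapping
precision would match. Suite problem sizes (registries up to a few
hundred entries, feeds of ~a dozen trials) were chosen so the whole suite
runs in seconds while still exercising every code path; the brute-force
equivalence checks are the same at any size.

## Degenerate inputs and tie-breaks

Unparseable structures queue for review (registration never raises on
data problems); a structure whose fragments are all dictionary salts has
no derivable parent and errors explicitly. Names matching multiple
legacy-duplicate entries queue rather than merge. Two equally specific
unrelated MeSH candidates for one phrase are both kept. Identifier
refresh rewrites downgraded ids automatically but queues merges and
removals for inspection. Exports render NULL as a literal `\N` so empty
string and absent value are never conflated, and all output tables are
sorted by id, making exports byte-deterministic given identical inputs.

## Known limitations

- The literal inorganic-element rule misclassifies simple inorganic
  halides and oxoacid salts that contain listed elements (documented
  above; kept as specified).
- Tautomer-sensitive parent derivation relies entirely on manual links.
- One active ingredient per prodrug; metabolite chains and multi-active
  conjugates store only the designated active component.
- V3000 molfiles are not read.
- The `is_indication` category vocabulary beyond {1 confirmed, 0
  rejected} is accepted opaquely.
- Black-box-warning classification from label text is out of scope; the
  flag is stored as a given annotation.
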