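# Methods

## The system being modeled

The larval episphere of the annelid *Platynereis dumerilii* develops from
the four first-quartet micromeres 1a–1d (collectively "1m"), born at the
16-cell stage (~2 hpf). Early development is spiral: successive oblique
divisions produce micromere tiers alternately rotated clockwise and
counter-clockwise, so the embryo is fourfold rotationally symmetric about
the animal–vegetal axis. From ~6 hpf, selected cells switch to bilaterally
oriented divisions; by ~32 hpf (>500 cells) the episphere is organized as
a patchwork of bilaterally symmetric clonal domains descending from 11
pairs of *bilateral founder cells*, plus rotationally symmetric structures
(the prototroch ciliary band) and asymmetric apical-organ cells that never
become bilateral.

The package implements (a) a synthetic-data generator that reproduces this
development as tracked lineage trees, (b) the cross-embryo
corresponding-cell algorithm with difference quantification and consensus
trees, (c) bilateral-founder detection, and (d) annotation/metric
utilities. All randomness flows from explicit integer seeds.

## Coordinate frame

Right-handed, apical pole at +z, dorsal at +y, the C quadrant toward +x.
The sagittal mirror plane is x = 0; the A and D quadrants lie on the left
(x < 0), B and C on the right. Quadrant sectors sit at azimuths A 225°,
B 315°, C 45°, D 135°, so the mirror maps the A sector onto B and C onto D
— the predominant left–right homology scheme. Lengths are in units of the
hemisphere radius (micrometres by convention, but treated as opaque);
times are hours post fertilization (hpf) throughout.

## The synthetic embryo

**Scripted phase (2–16 hpf).** The canonical division program is a
packaged fixture (`fixtures/events.tsv`): one row per division with
mother, time, mode (spiral cw/ccw, radial, bilateral, budding) and
daughter fate tags. It encodes the stereotypic episphere lineage: the
spiral tiers; per quadrant three primary prototroch cells (1m-221,
1m-222, 1m-212, cell-cycle exit 6.5–7 hpf) and three accessory prototroch
cells (1m-211, 1m-122, 1m-1212, last spiral divisions at 8.5 hpf), except
the D quadrant, which contributes only two accessory cells because the
1d-121 clone and 1d-1222 migrate out of the episphere through the gap in
the prototroch ring; the apical-organ events (1c-111 → ampullary cells at
9 hpf, 1d-111 → large dorsal apical cell and first axonal cell at 10 hpf,
1a-111 budding 1a-1112 at 9 hpf with 1a-1111 dividing at 12 hpf); the
first bilateral division (1m-112 at exactly 6.0 hpf) and the second tier
(1m-1121 at 8 hpf); and the stems leading to the 11 founder pairs.

**Founder registry.** `fixtures/founders.tsv` lists the 11 pairs with
origin times (6.0–13.6 hpf), symmetry classes, and a `verified` flag.
The lateral pairs (1m-1122-derived, ids 4/9), the A|C pair (1a-1211 /
1c-1211), and the two single-quadrant pairs (1a-1121211/1a-1121121 and
1b-12111aa/1b-121121b) have documented identities; the medial
non-corresponding pairs carry constraint-consistent but synthetic lineage
identities and are flagged `verified=false` — they should not be read as
biological claims.

**Growth phase (to 32–34 hpf).** Late development is parametric: each
founder clone (and a few other proliferative sublineages) grows as a
binary tree with per-clone mean cycle lengths — 3.1 h in the dorso-lateral
(*otx*-territory) clones, 3.5 h ventro-laterally, 5.0–5.5 h medially,
6.5 h in the apical region — a deterministic ±15 % hash-derived cycle
spread, and a per-division terminal-differentiation probability
(0.03–0.25). These defaults make the lateral territory the most
proliferative (deepest lineage, shortest cycles) and carry the total past
500 cells at 32 hpf. The growth of each founder clone is generated once
for the left member and mirrored to the right member, so in the
stereotypic embryo left and right clones are exactly symmetric in
topology, times, and (reflected) positions.

**Geometry.** Every scripted cell has an explicit anchor (azimuth, polar)
on the unit hemisphere: ring layouts for the prototroch, a territory map
for founder clones (left-half territories, mirrored right), and twisted
positions for the spiral-phase cells. Two geometric choices matter:

- *Rotational structures are de-phased from the midline.* Ring and
  rosette cells sit at a phase offset (primary ring 7.5°, accessory ring
  11°, rosette 25°) so the sagittal mirror maps each ring cell into the
  gap between cells on the other side. This reflects that the midline
  passes between prototroch cells, and it is what keeps the (terminal,
  synchronous, rotationally placed) prototroch and apical-organ cells out
  of founder pairs.
- *Growth clones stay compact* (≤0.05 R around their territory center,
  sibling offsets 0.03 R) and territories are ≥0.2 R apart, so clones
  never wander into the mirror image of another clone.

Positions are sampled every 0.5 h (static anchor + optional noise);
daughters sit at their anchors from birth.

**Variability model.** Four components, all off in the zero-variability
("canonical") embryo, which is bit-identical across seeds:

| parameter | default | meaning |
|---|---|---|
| `sigma_max` | 2.05 h | division-time jitter s.d. at 32 hpf; σ(t) rises linearly from 0 at 2 hpf |
| `deviation_onset` | 16 hpf | earliest time lineage deviations appear |
| `deviation_rate` | 0.155 | per-cell probability (cells born after onset) of a skipped division (a would-divide cell differentiates) or an extra division (a terminal cell divides once) |
| `position_noise` | 0.02 R | per-timepoint isotropic positional noise |
| `b111_probs` | (1/2, 1/3, 1/6) | ventral rosette cell 1b-111: no / one / more divisions, first division uniform in 12–24 hpf |

Jitter is drawn per division but keyed by the *left-counterpart identity*
of mirrored clones: left/right homologs inside one embryo stay
near-synchronous (as they do in a real embryo) while different embryos
draw independently. Deviations remain independent per cell — they are the
genuine left/right and between-embryo differences.

*Calibration.* `sigma_max` is set so that the mean max-minus-min division
time across a 3-embryo cohort reaches ≈2.5 h in the 30–34 hpf window; the
naive value (2.5/1.693 = 1.48, from the expected range of three normal
draws) undershoots because divisions jittered past the recording end are
censored out of the statistic, so the default is higher. `deviation_rate`
is set so that ≈10 % of cells at 30 hpf are absent from both other cohort
members. Note that under the strict "absent from both others" rule a
*skipped* division is invisible (the subtree missing from one embryo is
still present in the other two), so the 10 % is carried by extra
divisions and by 1b-111; skips instead surface as support-2 nodes in the
consensus tree. Randomness uses counter-based (Philox) streams namespaced
per seed and per cell, so adding events never shifts unrelated draws, and
the canonical phase uses seed-independent hash-derived draws.

**What the generator does not emulate.** No cell mechanics, signaling, or
migration dynamics (migrating cells simply leave after a fixed delay); no
hyposphere; positions are anchored rather than emergent, so cell
neighborhoods do not rearrange; deviations are memoryless single events
rather than heritable lineage changes; division-time jitter is Gaussian
and uncorrelated across divisions of one cell line. Tests passing on this
generator therefore demonstrate the *algorithms* (matching, censoring
logic, detection, statistics) under the documented variability structure,
not performance on microscopy-derived tracks with segmentation errors,
drift, or missed divisions.

## Corresponding-cell matching

Matching starts from user-assigned root pairs (the four quadrant
micromeres in the pipeline). At each matched pair in which both cells
divide, per-daughter features are extracted: the unit offset of each
daughter from the mother (positions averaged over a 1-h window around the
division to suppress per-timepoint noise), the daughter's subsequent cycle
length (censored with its observed lower bound if it never divides within
the recording), and its descendant count within the comparison horizon.
The two possible daughter assignments are scored with

    s = [ w_pos Σ (1+cos θ)/2 + w_cycle Σ K(c₁,c₂) + w_desc Σ (1 − |n₁−n₂|/max(n₁,n₂,1)) ]
        / ( 2 (w_pos + w_cycle + w_desc) )

where K is `exp(−|c₁−c₂|/τ)` for two observed cycles, `exp(−max(0, b−c)/τ)`
when one is censored at bound b, and 1 when both are censored. Defaults:
equal weights, τ = 2 h. The original weighting constants were never
published, so these defaults reproduce the *behavior class* of the
procedure; they are configurable. Exact ties go to the assignment with
the smaller summed offset angle, then to index order. The winning
assignment re-roots the recursion (greedy, no backtracking — a wrong
choice propagates down its subtree, as in the original procedure).

**Censoring.** Recordings end while divisions continue, so embryos are
compared at `t_compare` (default 30 hpf) with the remaining frames up to
`t_compare + guard` (default 3 h) used as known divisions to come. A
division before `t_compare` in one embryo with no counterpart within the
guard window — while the guard window was fully observed or the cell
visibly differentiated — marks the dividing side's subtree as a *real
difference*; if the recording ends first, the subtree is *censored* and
never counted. Truncating a recording can therefore only convert real
differences into censored ones, never create them.

**Differences.** A cell counts as differing at time t when it (or its
originating division) is flagged as a real difference against *both*
other cohort members; the report carries per-embryo counts, totals, the
pooled percentage, and the identities of the differing cells.

**Consensus.** Matched cells across the cohort are grouped by union–find;
a class containing two cells of one embryo indicates contradictory
pairings (an error by default; droppable in noisy pipelines). Divisions
are retained with majority support (≥2 of 3); nodes carry support counts,
division-time ranges (min, max), propagated names where all members
agree, reference IDs (`r1`, `r2`, … assigned in breadth-first birth-time
order), and a low-support flag for branches seen in only 2 of 3 embryos.

**Asynchrony.** For every corresponding division observed in all cohort
members, the max-minus-min of the member times; the statistic is the mean
over divisions whose mean time falls in the query window.

## Bilateral-founder detection

Candidates are cross-side cell pairs satisfying the three criteria with
quantitative defaults: birth times within `dt_tol` = 1.0 h; mirror
distance (birth positions averaged over 30 min, left position reflected
through the plane) within `mirror_eps` = 0.10 of the hemisphere radius;
clone-topology similarity ≥ `topo_min` = 0.8. Topology similarity is a
strictly nested recursive match: two divisions match only inside matched
parents and only if their clone-relative times differ by ≤ `dt_tol`;
score = 2·matched/(divisions_u + divisions_v), defined as 1.0 for two
terminal cells. Candidates are pruned to the earliest qualifying
generation (no candidate pair among their ancestors) because every
descendant pair of a founder pair also qualifies; each cell joins at most
one pair (greedy by descending topology score, then smaller mirror
distance, then lexicographic id). The thresholds were chosen so the
stereotypic embryo yields exactly its founder registry; they are
reported in the output and configurable.

Two practical notes. (1) The mirror-plane estimator minimizes symmetric
nearest-neighbor distance over plane azimuths (1° scan + bounded
refinement). Before ~16 hpf the rotationally symmetric rings dominate the
point cloud and possess their own pseudo-mirror planes, so on noisy
embryos the fit is reliable from ~20 hpf on (the CLI fits at 24 hpf by
default); on the stereotypic embryo it recovers the sagittal plane
exactly at 12 hpf. (2) On embryos with heavy lineage deviations the
topology score of a true founder pair can fall below threshold (a skipped
division early in one clone removes a whole subtree of matches), after
which its descendants surface as many small mirror pairs. Detection is
meant for the stereotypic phase — run it on zero-variability or
consensus-grade data; the 11-pair result refers to the canonical embryo.

## Annotations, metrics, clonality

The packaged table lists the 62 differentiated cell types of the 30-hpf
episphere (12 primary + 11 accessory prototroch records, head kidneys,
migrating cells, 5 gland cells, 4 apoptotic cells, apical-organ cells,
larval eyes, and 9 cholinergic, 9 neuropeptidergic and 3 serotonergic
neurons), with consensus lineage names (printed commas normalized away),
reference IDs, support counts, approximate cycle-exit times, and markers
extracted into an explicit column at transcription time. One printed row
covers two anterior prototroch cells and is stored once with
multiplicity 2; one late cholinergic cell has a variable terminal lineage
(stored with its stable prefix plus a `variable_suffix` field and its
double reference ID).

Lineage depth counts divisions from the zygote (trees rooted at the 1m
quartet add offset 3: zygote → AB/CD → quadrants → 1m); cell age is time
since birth; cycle length is the lifetime of a divided cell. The
clonality analysis projects labeled cells forward by pure clonal
expansion and scores the observed expression against the projection with
the Jaccard index (1.0 ⇔ perfectly clonal; genes that switch on/off
between cycles score lower), reporting gained and lost cells.

## Problem sizes and determinism

The acceptance script simulates one canonical embryo (~1950 cells to
32 hpf), five default-variability embryos, and ten 3-embryo cohorts to
34 hpf with three pairwise matchings each; it runs in under a minute on a
single CPU. The full test suite (147 tests, including brute-force
equivalence checks of the matcher and the founder detector and a
1000-name grammar round trip) runs in about 40 s. All stochastic results
are reproducible bit-for-bit given the seed.

## Known limitations

- The medial founder identities (pairs 1, 2, 3, 5, 7, 8) are synthetic
  stand-ins consistent with the documented constraints, flagged
  `verified=false` in the registry.
- The difference metric follows the strict absent-from-both-others rule;
  metrics that also count majority-supported absences would weight
  skipped divisions differently.
- Founder detection and mirror-plane fitting degrade on heavily deviated
  embryos (see above); they are stereotypic-phase tools.
- The expression-label registry holds user-supplied labels only; no gene
  atlas contents ship with the package.
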