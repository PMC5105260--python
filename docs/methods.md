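# Methods

## Curation

Input libraries (SMILES or SDF) pass through a deterministic, idempotent
standardization before any metric is computed:

1. split multi-component records (salts, mixtures) into connected
   components;
2. keep the component with the most heavy atoms that contains at least one
   carbon — ties broken by the lexicographically smallest canonical SMILES,
   so re-runs are reproducible; records with no carbon-containing component
   (pure inorganic salts) are rejected with a reason code;
3. neutralize formal charges wherever a proton can be added or removed
   without changing connectivity (RDKit `Uncharger`); quaternary
   ammonium-type centers keep their charge;
4. re-canonicalize, then deduplicate on the canonical SMILES (first
   occurrence wins). The library size M always counts unique curated
   compounds.

This is a deliberate simplification of full commercial "wash" protocols:
no salt dictionaries, no protonation-state enumeration, no tautomer or
stereo normalization (stereo is preserved as given). The downstream metrics
only require a deterministic standardization, not a chemically exhaustive
one; the neutralization rule in particular is a documented stand-in for the
under-specified notion of "rebalancing protonation states".

## Chemotypes

The chemotype of a molecule is its framework: iteratively delete terminal
(degree-1) heavy atoms until none remain, keeping atom and bond types (no
generic-graph abstraction). Molecules with no rings map to the single
shared `ACYCLIC` sentinel rather than each being its own chemotype — this
matches the observed behavior of acyclic-rich libraries, where a large
fraction of a set shares "the same chemotype" and scaffold diversity is
correspondingly low, and it makes the cyclic-subset operation
(`--subset cyclic`) meaningful.

Pruning is performed on the kekulized graph so that removing a substituent
or an exocyclic double-bonded atom from an aromatic ring cannot strand
aromatic-perception state; aromaticity is re-perceived afterwards. A
2-pyridone-type ring that loses its carbonyl oxygen therefore re-emerges
as the corresponding non-aromatic ring framework, which is the intended
reading of "delete terminal atoms until none remain".

Exocyclic double-bonded atoms (carbonyl O, imine N on a ring) are pruned by
default, because they are degree-1; conventions differ between toolkits, so
`keep_exocyclic=True` (CLI `--keep-exocyclic`) retains any terminal atom
attached through a non-single bond.

## Scaffold-diversity metrics

* **CSR curve**: chemotypes sorted by descending count (ties by ascending
  key, so output is deterministic); point k is
  (k/N, cumulative compound fraction), anchored at (0, 0).
* **AUC**: trapezoidal integration of that piecewise-linear curve is the
  default; it makes an all-singleton library score exactly 0.5 (the
  diagonal) and is bounded above by 1, a limit approached — never reached —
  as compounds concentrate into one chemotype. A staircase convention
  (Σ (1/N)·y_right) is available for comparison with step-function readings.
* **F50**: the smallest k whose cumulative compound fraction reaches 1/2,
  divided by N; a discrete coverage count, no interpolation.
* **SE/SSE**: entropy in bits over the n most populated chemotypes; n is
  clamped to N, the population P is renormalized to the selected
  chemotypes, and SSE = SE/log₂(n_selected) with SSE ≡ 0 for a single
  selected chemotype. The profile grid defaults to n = 5, 10, …, 70.
* **Count ratios** are computed in exact rational arithmetic and reported
  at 3 decimals with round-half-even, so printed ratios are reproducible
  from integer counts alone.

## Fingerprint metrics

MACCS keys use RDKit's 167-slot implementation (slot 0 unused, keys
numbered 1–166); ECFP4 is the Morgan fingerprint of radius 2 hashed to
2048 bits — a width at which collisions are negligible at the library sizes
involved; the toolkit version is recorded in the run manifest. All
M(M−1)/2 pairs are enumerated; there is no similarity sampling. Quartiles
use linear interpolation between order statistics (the convention of
standard statistical environments) and SD is the sample standard deviation
(n−1); a single-pair library reports SD 0 with `sd_defined=False`. Two
empty fingerprints score Tanimoto 0 (with a warning): a featureless pair
carries no evidence of identity.

## Property metrics

Descriptors are RDKit's published open algorithms (Wildman–Crippen logP,
Ertl TPSA, standard donor/acceptor/rotatable-bond counts); values differ
slightly from proprietary descriptor engines and the versions are pinned in
the manifest. The rotatable-bond count uses the strict definition under
which ethanol's terminal hydroxyl does not rotate (RTB = 0).

I_uv distances are computed after pooled z-scoring: each of the six columns
is centered by the mean and divided by the sample SD of the *pooled*
population of all compared sets (zero-variance columns are centered with
unit divisor and flagged). Raw MW (hundreds of Da) and TPSA (tens of Å²)
would otherwise dominate the count descriptors entirely; scaling also makes
distances comparable to the ~1–3 range typical of z-scored six-descriptor
profiles. `--no-scale` disables it. The intra-set case applies the I_uv
formula verbatim — self-pairs included, divisor U² — with an
`exclude_self` option. Exact symmetry of I_uv in (u, v) is guaranteed by
summing the sorted distance multiset, which fixes the floating-point
summation order.

## Consensus plot

Fingerprint diversity is HIGH iff the median similarity is strictly below
the x threshold; scaffold diversity is HIGH iff the y metric beats its
threshold in the metric's own direction (AUC: below; F50/SSE: above).
Values exactly on a threshold classify as LOW — a conservative, documented
tie rule. `"median"` thresholds resolve to the median of that metric over
exactly the compared sets, so classification is relative to the comparison
at hand; resolved numbers are written into the companion TSV and printed on
the plot. Point *area* is proportional to M (radius ∝ √M, the standard
perceptual choice) and the property-distance color ramp is a three-point
linear green → orange/brown → red scale normalized min–max over the
compared sets (red = most property-diverse). The x-axis plots similarity
itself, labeled "lower = more diverse", to avoid orientation ambiguity.

## Synthetic libraries

The generator exists so that every metric can be validated against exact
ground truth. Its pool holds 124 ring systems that are *framework-stable*:
each pool entry equals its own chemotype, which the test suite verifies.
Molecules are built by attaching 1–`decoration` substituents from a fixed
acyclic menu (alkyls, halogens, hydroxyl/alkoxy, amino, nitrile, CF₃,
thio…) at hydrogen-bearing scaffold atoms; because an acyclic substituent
can neither create nor destroy a ring, the chemotype of every product is
provably the chemotype of its bare scaffold. Ring-free members are short
heteroalkyl chains (3–9 atoms, no adjacent heteroatoms) and map to
`ACYCLIC`.

Chemotype populations are controlled directly: uniform, explicit count
lists, or Zipf weights i^(−s) (largest-remainder rounding with one molecule
reserved per scaffold) — increasing s concentrates the library, raising AUC
and lowering SSE, which the tests check. The most populated chemotypes are
assigned to the scaffolds with the most substitution sites so that large
analog series are always constructible; within a series, molecules are
found by seeded rejection sampling over decoration choices and
deduplicated on canonical SMILES, so a fixed spec (including its seed)
yields byte-identical output. `acyclic_fraction` f contributes exactly
round(f·n_molecules) acyclic molecules.

What the generator does *not* emulate: realistic medicinal-chemistry
property distributions, stereochemistry, salt forms, tautomers, or
scaffolds outside its pool. Passing tests on synthetic libraries therefore
demonstrate the correctness of the bookkeeping and the metrics, not the
field behavior of any real screening collection.

## Numerical and scale choices

Default problem sizes keep the complete test suite in the tens of seconds:
ground-truth recovery runs at 10³ molecules, oracle agreement at 10³ random
chemotype tables (AUC and SE against brute-force sums, ≤ 1e−12), I_uv
against a double loop at U, V ≤ 30. Pair enumeration is O(M²) by design —
the method prescribes all pairs — and is practical to the ~10³–10⁴
molecule range typical of the libraries this analysis targets.

Known limitations: the chemotype definition is a framework derivation, not
a reimplementation of proprietary chemotype-naming programs, so chemotype
*keys* are canonical SMILES rather than short codes; MACCS key definitions
vary slightly across toolkits; descriptor values differ from proprietary
engines; and the quadrant classification is relative to the compared sets
whenever median thresholds are used.
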