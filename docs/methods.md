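# Methods

## Consensus model

A protease is modelled as an ordered list of residue-constraint sets
over the 20 standard amino acids plus a cleavage offset: a singleton set
pins a position, the full set is the wildcard `X`, any other subset
expresses alternatives. The scissile bond lies after pattern position
`cleavage_offset` (1 ≤ offset ≤ pattern length). This covers the
built-in caspase-3 (`DXXD|`, offset 4) and calpain-2 (`[LVI]X|`, offset
2, one pattern equivalent to the LX/VX/IX family) and any user-defined
fixed/wildcard/alternative motif. Probabilistic models (position weight
matrices, cleavage-probability scores) are out of scope.

The number of literal words a motif matches is the product of its
position-set sizes (400 for caspase-3, 60 for calpain-2); this closed
form is cross-checked in the tests by brute-force enumeration of all
20^m words.

Non-standard letters (B, J, Z, U, O, X, `*`) never satisfy a fixed
position and by default do not satisfy a wildcard either, so ambiguity
codes cannot fabricate cleavage sites; a `permissive_wildcard` flag
relaxes the wildcard check only. Input sequences are canonicalised to
upper case on load.

## Scanning

The scanner builds a local-alignment scoring table of (m+1)×(n+1)
integer cells per (motif, substrate) pair: match +1, mismatch and gap
both −m, scores floored at 0. Occurrences are the last-row cells with
the maximal score m whose traceback is purely diagonal with a match at
every step; alignments containing insertions, deletions or a
fixed-position mismatch cannot reach score m and are thereby pruned.
The result provably equals a naive sliding-window scan, which is kept in
the package as an independent oracle; equivalence is property-tested on
seeded random substrates, including Asp/Glu-rich adversarial
compositions that maximise overlapping DXXD structure.

Numerical note: because the best attainable score in row i is i ≤ m, a
vertical or horizontal (gap) move contributes at most i − m ≤ 0 and can
never exceed the 0 floor. Each row of the table therefore reduces to
`max(0, diagonal + substitution)` and is filled with one vectorised
numpy operation, while remaining cell-for-cell the table the full
three-way recurrence defines (the frozen hand-computed table in the
tests checks this). Complexity is O(mn) time and space per pair; a
multi-protein scan streams one table at a time, so peak storage is
independent of the number of proteins.

Coordinates are 1-based and inclusive throughout. Hits abutting either
terminus are reported; a cut site falling after the last residue is
suppressed downstream (it would yield an empty product). An optional
context-window width pads the *displayed* consensus in reports without
altering coordinates — useful because validated sites are often quoted
with flanking residues (e.g. a 2-residue calpain core reported inside a
4-mer window).

## Digestion

Cut sites are the deduplicated cleavage positions of all occurrences;
overlapping occurrences contribute distinct sites, and sites from
different proteases falling on the same bond merge into one site with
multi-protease provenance (independent merge; protease competition or
ordered cleavage is not modelled). Three fragment views:

* `per-site`: one scenario per single cut, two fragments each — the
  layout of a classic cleavage table;
* `scenarios`: every non-empty subset of the k sites (each subset is a
  possible cleavage incidence), 2^k − 1 scenarios. Enumeration is
  refused above `max_sites` = 16 (65 535 scenarios) — the guard exists
  because subset enumeration is exponential while real substrates can
  carry hundreds of sites; callers may raise the cap or use the union;
* `distinct`: the union of fragments over all scenarios without
  enumerating subsets — every boundary pair from {0} ∪ sites ∪ {length}
  except the intact pair, i.e. (k+1)(k+2)/2 − 1 fragments in O(k²).
  The closed form is property-tested against subset-union brute force
  for k ≤ 10.

Every scenario's fragments partition the substrate exactly (lengths sum
to n, concatenation reconstructs the sequence); the intact protein is
not itself reported as a breakdown product. Output ordering is fully
deterministic (protein input order, then scenario, then start), so
reports are byte-identical across runs.

## Masses

Fragment mass = Σ residue masses + one water, computed with the standard
published residue masses for the 20 unmodified amino acids (average and
monoisotopic; water 18.0153 / 18.0105646863 Da). No PTMs or terminal
modifications. Hydrolysis conservation — Σ fragment masses = parent +
cuts × water — holds to 1e-6 Da and is asserted per scenario in the
tests; pyteomics serves as an independent cross-check of the mass sums.
Computed chemical masses are deliberately *not* reconciled with apparent
SDS-PAGE mobilities of named signature fragments (e.g. the
110/108/85/80 kDa spectrin breakdown products): gel mobility is not a
chemical mass, and no formula links the two.

## Synthetic data

`random_proteome(n, length_range, seed)` draws uniform random
amino-acid sequences — a desk-scale stand-in for whole-proteome runs.
Default lengths 50–500 match typical protein sizes; the property suite
uses 1000 records, which exercises the streaming scan at a size that
keeps the full test run to seconds. `plant_motifs` places concrete
words matching chosen motifs at recorded positions on a random
background (uniform by default, or caller-supplied residue frequencies);
in collision-free mode the background is re-rolled until a naive scan
recovers exactly the planted truth, giving an exact ground truth for
scanner benchmarks. Overlapping placements are supported by
intersecting the residue constraints of the covering motifs.

What the generator does not emulate: realistic proteome composition
(residue frequencies, domain structure, low-complexity regions),
sequence homology between records. Passing tests on synthetic data
therefore demonstrate algorithmic correctness (the scan finds exactly
the planted/true motif occurrences; fragment enumeration is exact), not
biological cleavage-site plausibility on real substrates.

One real substrate is embedded: a 775-residue mouse protein (record
`194`) whose Asp/Glu-rich region carries five DEED occurrences, three
mutually overlapping — the canonical overlap worked example. The
βII-spectrin substrate (GenBank accession M96803) is not embedded
(it is distributed as supplementary data, not printed text); its two
validated-cleavage tests run automatically when the user supplies the
FASTA at `tests/data/M96803.fasta`, and an always-runnable synthetic
surrogate of the same length with the validated motifs (DSID at 1251,
DEVD at 1454, ETVD at 2143) spliced at their reported coordinates
exercises the identical checks offline.

## Design choices and limitations

* The scoring scheme (match +1, mismatch/gap −m) is the package's own
  numerical choice; any scheme in which a single mismatch or INDEL makes
  the maximal score unreachable yields the same pruned occurrence set.
* Degenerate inputs: empty substrates produce an all-zero table and no
  hits; substrates shorter than the motif produce no hits; a protein
  with no cut sites digests to an empty fragment list (header-only
  report).
* Kinetics, cleavage order, missed-cleavage probabilities and protease
  competition are not modelled; all cut-site subsets are treated as
  equally possible, which is a combinatorial statement, not a kinetic
  one.
* The CLI (`scan`, `digest`, `patterns`, `fixture`) is a thin layer over
  the library; exit codes are 0 (success), 2 (input error), 3
  (combination-explosion guard).
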