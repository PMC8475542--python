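# Methods

## Scoring model

A docked pose's binding site is the set of receptor residues with at least
one heavy atom within 3.5 Å (inclusive) of at least one ligand heavy atom.
The cutoff is a contact definition, not a fitted parameter; hydrogens are
excluded on both sides by default because typical inputs (crystal
structures, docking output) are inconsistent in hydrogen presence, and
determinism across sources matters more than the marginal contacts
hydrogens would add. A flag re-includes them.

The Conservation Score of a site is the unweighted arithmetic mean of its
residues' conservation values cₖ ∈ [0, 1]; averaging is per residue, not
per contacting atom. The combined score is the exact product of the
Conservation Score and the docking program's energy score (e.g. SwissDock
FullFitness), with no rescaling, clamping or z-normalisation across poses.
With negative energies the product is monotone in both inputs: more
conserved sites and better energies both drive it more negative, and the
most negative product is the predicted binding site. A positive energy
inverts this ordering, so it is scored as-is but flagged with a warning.
Ranking ties (exact score equality) break by ascending energy, then pose
id, making output order total and reproducible. Poses whose site is empty,
or none of whose site residues carry a conservation value, are excluded
from ranking and reported with a reason code; by default a site residue
with no mapped conservation is simply dropped from the mean (a strict mode
raises instead).

## Conservation

Two sources produce the per-residue profile:

* **Imported grades.** A whitespace-delimited table of integer grades 0–9
  per sequence position (9 = fully retained). Grades are normalised by
  exact division by 9, so value × 9 recovers the integer bit-for-bit; the
  raw grades are retained alongside. The Bayesian phylogenetic machinery
  that produces such grades is an external tool's contribution and is not
  re-implemented here.
* **Internal JSD scorer.** For an alignment column with residue frequency
  distribution P (gaps excluded) and background B, the score is
  JSD(P, B) = ½KL(P‖M) + ½KL(B‖M) with M = ½(P+B), base-2 logs, which is
  bounded by 1 bit and therefore already lies in [0, 1]. A pseudocount of
  1/(20·n_seq) is added to the relative frequencies (then renormalised)
  rather than to raw counts: this keeps a column identical to a uniform
  background at exactly 0 and makes the gap penalty an exact multiplier.
  With the gap penalty on (default) the score is multiplied by the
  column's non-gap fraction. Backgrounds: uniform over the 20 residues
  (default) or the BLOSUM62 amino-acid frequencies. 'X' and other unknown
  letters are excluded from P but count as non-gap for the gap fraction.
  No window smoothing is applied; columns are scored independently.

Scores are carried to the structure by global sequence alignment
(BLOSUM62, gap open/extend 10/0.5) of the structure's one-letter sequence
against the score sequence; mappings below 80% identity over aligned
positions are rejected, a letter mismatch at an aligned position warns but
still assigns, and structure residues with no aligned score simply carry
no entry.

## Evaluation metric

The benchmark distance is between centers of mass of the predicted
(rank-1) and reference ligand coordinates. Mass weighting with standard
atomic masses is the default; an unweighted centroid is available because
both conventions circulate in the docking literature and they coincide for
homo-elemental ligands. A configurable success threshold (default 4.0 Å)
summarises a batch; it is a reporting convenience, not part of the score.
Residue-set agreement between the predicted site and the reference pose's
own 3.5 Å site is reported as the Jaccard index (undefined and reported as
missing when both sites are empty). Matched-atom RMSD is available only as
a diagnostic when atom counts happen to match; no symmetry correction is
attempted, since the method predicts sites, not poses.

## Synthetic scenarios

The generator emulates the structure of the real problem rather than its
chemistry. The receptor is a poly-alanine bundle: residues on a cylinder
lattice (radius 8.5 Å, 8 columns, 3.0 Å rise per row, 0.3 rad twist per
row), each a rigid 5-heavy-atom unit (N, CA, C, O, CB) with CB pointing
into the central cavity — a cartoon of a seven-helix receptor's
extracellular cavity. A pocket is planted just inside the cavity wall:
the `pocket_fraction` (default 0.2) nearest residues to an anchor point
3.0 Å inside an upper-wall CB. The ligand is a fixed rigid 8-heavy-atom
cluster (cube corners, mixed C/N/O), deliberately not a valid molecule:
contact and center-of-mass arithmetic need no chemistry, and this keeps
cheminformatics out of the test path.

Conservation is planted as per-column retention probabilities: pocket
columns at `pocket_conservation` (default 0.9), the rest at
`background_conservation` (default 0.2). Each non-target alignment
sequence keeps the target letter with that probability or mutates to one
of the 19 others; grades are round(9 × level). The default alignment depth
is 50 sequences. Decoy energies are drawn from Normal(−3400, 100), the
scale of SwissDock FullFitness values; the true pose's energy is placed at
a chosen percentile of the realised decoy energies (default 0.7, i.e.
*not* the energy-best), which is what makes the rescue behavior testable:
energy-only ranking picks a decoy, conservation weighting recovers the
planted pose. Decoys are placed 4 Å outside the bundle wall at non-pocket
residues, with rejection sampling enforcing a non-empty contact site that
overlaps the pocket by < 20%. Every artifact is a pure function of the
`ScenarioSpec` (seed included); written files are byte-identical across
runs, and a manifest allows exact regeneration.

What the synthetic fixtures do **not** emulate: real side-chain packing
and pocket concavity, ligand flexibility and chemistry, correlated
evolution, alignment errors, and the accuracy limits of homology models.
Passing tests therefore demonstrate the correctness and the discriminative
mechanism of the scoring pipeline — not field performance on real
receptors, which additionally depends on docking quality and alignment
curation.

## Numerical choices

* Distances are inclusive (≤ cutoff); at the 0.001 Å precision of PDB
  coordinates the boundary case carries no measure.
* Contact search uses a KD-tree over receptor atoms; tests hold it to
  exact set equality with a brute-force all-pairs oracle.
* Coordinates are written at PDB precision (3 decimals) and treated as Å
  throughout; round-trips are exact at that precision.
* Alternate locations resolve to the highest-occupancy conformer, ties to
  the first encountered; multi-model receptors default to the first MODEL.
* SwissDock-style cluster files assign the cluster-level FullFitness to
  every member pose; a flag keeps only cluster representatives, since
  which of the two a given workflow wants varies.
* Problem sizes in tests and the acceptance script (50-residue contact
  fixtures, 200 rescue scenarios, 100-column recovery alignments) were
  chosen so the full suite runs in seconds while estimates remain stable
  to well within the asserted margins.

## Known limitations

* ConSurf-style grades are imported, never recomputed; the JSD scorer is
  a documented alternative, not a re-implementation of Bayesian
  rate estimation.
* The exact normalisation by which external tools map 0–9 grades to the
  decimal site conservations they report is not standardised; grade/9 is
  used here and both the normalised value and the raw grade are kept.
* Conservation is averaged per residue; atom-level weighting of contacts
  is not implemented.
* mmCIF input, structure preparation (protonation, minimisation) and
  running any docking engine are out of scope; the package rescales
  nothing about the docking program's energies and inherits their quality.
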