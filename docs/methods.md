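# Methods

This note records the models, conventions and numerical choices behind
`cladeface`, and what its synthetic benchmarks do and do not demonstrate.

## Sequence curation

Full-length helper-NLR candidates are kept when their ungapped length lies
in [750, 950] residues, and NB-ARC domains when the annotated span lies in
[300, 400]; both windows are inclusive on both ends, the conventional
reading of "between X and Y". Domain ranges are inputs (1-based inclusive,
ungapped coordinates) — the package does not run domain annotation itself,
and records lacking a range are dropped with an explicit report rather
than silently.

Deduplication collapses *exact* full-length identity only, keeping the
first occurrence as representative. Clustering tools at 100% identity may
additionally collapse a sequence into a longer sequence that contains it
as a substring; we deliberately do not, because exact identity is
parameter-free and idempotent. Datasets curated with substring-collapsing
tools may therefore retain slightly fewer sequences than ours.

Clade assignment automates what is often done by eye on a tree viewer:
for each named clade, we take the *smallest* internal branch that contains
all of that clade's reference leaves, none of any other clade's, and
carries a support value at or above the threshold (default 0.8 — "well
supported" is rarely quantified in the literature; the value is
configurable and echoed in the run manifest). Branches without a support
value never qualify; missing support is treated as missing, not zero.
Leaves covered by no qualifying branch stay unassigned, matching the
practice of excluding sequences that fall between major clades. Reference
pairs that no branch can separate are reported and both clades left
unassigned. The rule operates on the rooted form of the input newick; it
does not enumerate the complement side of each bipartition.

## Column statistics

All column statistics run over the 20-letter amino-acid alphabet with a
single gap character (`.` is normalised to `-` on read). Gaps and the
ambiguity code `X` are excluded from numerator *and* denominator, so a
column's effective sample size is its non-gap count. This keeps the 80%
frequency rule (below) independent of gappiness; the alternative
(gap-inclusive denominators) would make callability decay with alignment
raggedness.

**Trimming.** Columns whose gap fraction is ≥ 0.9 are removed (the
boundary value is removed, matching gappy-mode trimmers at their
documented default). The retained→original column map is carried through
every downstream table so positions can always be reported in the original
frame.

**Stretch mapping.** Residue ranges given in reference-sequence numbering
are mapped by walking the reference row and skipping its gaps. When
mapping onto a trimmed alignment, the column map is used to report any
stretch residue whose column was trimmed away (with its original column)
instead of silently shifting. The built-in table of eight dimerization
stretches spans 44 reference residues.

**Entropy.** Plug-in (maximum-likelihood) Shannon entropy in bits,
−Σ p log₂ p, bounded by 0 and log₂ 20 ≈ 4.32. No small-sample bias
correction is applied: the bounds quoted throughout are plug-in values,
and with subsets of a few dozen sequences the correction would be smaller
than the between-clade differences of interest. The variability
classification is strict: a column is "highly variable" only when
H > threshold (default 1.5 bits, a convention from NLR diversity
analyses); H exactly at the threshold is conserved. All-gap columns are
undefined, never zero.

## The relative amino-acid ratio

For a query clade Q against the pooled remaining clades S of a chosen
comparison set:

1. The column is callable only when Q's majority amino acid exceeds the
   frequency cutoff (strictly > 0.8). At any cutoff above 0.5 at most one
   amino acid can qualify, so "one of the frequencies is more than 80%"
   is equivalent to testing the majority residue.
2. ratio = freq_Q(aa) / freq_S(aa), with S pooled across sequences (one
   frequency vector), not averaged per clade.
3. unique ⇔ ratio > 50 (strict) or the amino acid is absent from S, in
   which case the ratio is reported as the token `INF` — never as a large
   numeric sentinel, so downstream thresholds stay honest.
4. A column where every Q row is a gap yields `NA`.

Raising the ratio cutoff can only shrink the unique set; raising the
frequency cutoff can only shrink the callable set (both verified as
property tests). The statistic is a threshold rule, not a significance
test; no correction for phylogenetic non-independence is attempted.

## Synthetic families

The generator emulates the statistical structure the analysis assumes: a
clade-partitioned family where background columns are either
family-invariant (probability 0.5 by default — enough of both kinds to
exercise both entropy extremes) or uniformly variable over the 20 amino
acids, plus planted clade-diagnostic columns. A planted site assigns the
clade residue to an *exact* rounded fraction (the fixation, in (0.8, 1])
of query rows and to an exact rounded fraction (the leak, in [0, 0.02))
of subject rows, with the background residue elsewhere; which rows is
randomised. Exact counts rather than Bernoulli draws make the planted
frequencies — and hence the expected ratios — reproducible at any sample
size. Gaps are inserted independently per character afterwards (default
5%), and optional end-trimming emulates length variation. The companion
tree is a star of clades: support 1.0 on every clade stem, unlabeled
within-clade ladders, so reference-guided extraction recovers exactly the
generating partition.

The default benchmark scale is 3 clades × 40 sequences × 300 columns with
5 planted sites per clade — comparable to the clade sizes (tens of
sequences) and NB-ARC-scale column counts of real helper-NLR datasets,
while keeping a 20-replicate run under a few seconds.

What passing these benchmarks shows: the caller finds exactly the planted
diagnostic columns at full fixation with zero leak, and still clears the
50-fold threshold in the leaky regime (85% fixation, 1.5% leak, where the
expected ratio is ≈ 0.85/0.013 ≈ 65). What it does not show: behaviour
under realistic substitution processes, indel evolution, phylogenetic
autocorrelation within clades, or alignment error — variable columns here
are i.i.d. uniform, which is *harder* to call falsely than real
covariation but *easier* than systematic alignment artefacts.

Toy dimers place one carbon pseudo-atom per residue so that exactly the
configured residue pairs sit at (cutoff − 0.5) Å and every other
inter-chain distance exceeds 30 Å; a residue may appear in at most one
contact pair (the linear layout cannot honour arbitrary shared-residue
contact graphs, and rejects them rather than approximating).

## Structure interface

Contacts use heavy atoms only — cryo-EM models at moderate resolution
carry no reliable hydrogens — with residue-residue distance defined as
the minimum over heavy-atom pairs and an inclusive 6 Å cutoff; the
permissive any-atom reading captures both short- and long-range
interactions. Ligands and waters are excluded by default (a flag includes
het-groups); only the first model and altloc ''/'A' are read. Van der
Waals radii come from a fixed table (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, default 1.70 Å) so areas are reproducible across inputs that do
or do not annotate elements.

Stretches: every interface residue is labeled by the partner-chain
domain(s) it contacts (domain boundaries are *inputs*, per chain, since
schematic domain definitions vary); maximal runs of consecutive residue
numbers within each (own-domain, partner-domain) class form stretches,
named in ascending residue order. Contiguous residues contacting
different partner domains split into separate stretches by construction;
a residue contacting two partner domains joins both classes.

SASA is Shrake–Rupley: for each atom, test points on the sphere of radius
(vdW + 1.4 Å probe), count the fraction inside no neighbour's expanded
sphere, scale by the sphere area. The point set is a deterministic
Fibonacci spiral lattice — no RNG, so areas are bit-reproducible — with
960 points by default (lone-sphere closed form reproduced well within 1%;
doubling the density moves the toy-dimer total by < 0.5%). Neighbour
search uses a k-d tree with radius expanded_i + max(expanded), which is
exact. Buried surface area per protomer is SASA(chain alone) − SASA(chain
in complex) computed at identical coordinates; tiny negative values from
lattice discretisation are clamped to zero. The total is the sum over
protomers. Because the lattice has a fixed orientation, exactly symmetric
dimers show a sub-percent numerical BSA asymmetry; tests assert equality
to 1%.

## Pipeline determinism

Reruns with identical inputs and configuration are byte-identical: all
randomness is seeded, the SASA lattice is deterministic, and the run
manifest records parameters and input digests but no timestamps. Stage
failures are reported with the stage name; outputs of completed stages
are retained.

## Known limitations

- Alignment and tree construction are out of scope: aligned FASTA and
  newick are inputs. Column coordinates are alignment-dependent; the
  manifest records input digests but cannot normalise across aligners.
- Clade extraction automates a manual practice; at poorly supported
  branches it may differ from expert curation by a few marginal
  sequences, which can flip borderline ratio calls near the 50-fold
  threshold.
- Exact deduplication retains length-variant near-duplicates that
  substring-collapsing clustering would remove.
- BSA depends on atom selection (ligands, altlocs) and the radius/probe
  convention; values should be compared across tools only to within a few
  percent.
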