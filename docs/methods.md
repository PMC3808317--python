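# Methods

This note documents the models and procedures implemented in `mirstress`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and known limitations.

## Read cleaning

A raw small-RNA read is modelled as insert + 3′ adapter, possibly
preceded by 5′-adapter contamination. Rules are applied in a fixed order
so the per-rule rejection tally is deterministic:
5′-adapter contaminant → no insert → poly(A) → length.

* The 3′ adapter is located by the leftmost occurrence of its first 8
  bases; a read whose adapter starts at position 0 is an adapter dimer
  ("no insert"), and a read shorter than the seed is treated the same
  way. Reads in which the seed never occurs are kept untrimmed — this
  choice makes cleaning idempotent (re-cleaning cleaned output is a
  no-op), which is tested.
* Poly(A): an insert is discarded when ≥ 80 % of its bases are adenine or
  it contains an A-homopolymer of ≥ 10 nt. The thresholds are a package
  definition; sequencing protocols do not standardize one.
* Length window 15–30 nt by default (configurable); U is normalized to T
  on ingest and re-emitted as U only in miRNA-facing reports.
* Adapters have no universal default and must be supplied; the bundled
  simulator uses standard Illumina small-RNA adapter sequences.

## Annotation

Mapping is perfect-substring matching on both strands (1-based
coordinates). ncRNA classification matches tags against labelled
rRNA/tRNA/snRNA/snoRNA records; multi-class hits resolve by the fixed
priority rRNA > tRNA > snRNA > snoRNA, and classified tags are excluded
from miRNA calling. Known-miRNA assignment compares each tag to every
known mature end-to-end without gaps: distance = Hamming distance over
the common 5′ prefix plus one per overhanging base, G:U counting as a
mismatch (unlike degradome scoring). A tag is assigned to the member
with the fewest mismatches (≤ 2 by default); ties break to the
lexicographically smallest member id so results are reproducible.
Known-miRNA assignment deliberately does not require a reference hit
(many plant references are incomplete); a strict mode can require one.

Family names are derived by stripping the species prefix and any
letter/arm suffixes after the family numeral (`ath-miR156a-5p` → miR156).

## RNA folding

Secondary structure is predicted by a Zuker-style dynamic program over a
deliberately simplified nearest-neighbour model:

* stacking energies for all 36 pair-on-pair combinations of the six
  canonical pairs (AU, UA, CG, GC, GU, UG), with Turner-like magnitudes
  (−0.2 … −3.4 kcal/mol);
* linear hairpin penalty 5.0 + 0.30·(size − 3) kcal/mol, minimum loop
  3 nt; linear bulge (3.6 + 0.30·size) and interior (2.0 + 0.30·size)
  penalties, at most 30 unpaired bases per loop;
* affine multiloops (3.4 closing + 0.40 per branch + 0.10 per unpaired);
* exterior bases free; no dangles, coaxial stacking or special hairpins.

The model is intentionally small enough that the DP optimum can be
verified against exhaustive enumeration of every nested structure on
short sequences — `structure_energy` scores an explicit structure by
direct loop decomposition and is the single definition of the model; the
enumeration oracle in the test suite uses it independently of the DP
recurrences. The inner loops are numba-JIT-compiled when numba is
importable and run as plain Python otherwise (identical results). An
alternative thermodynamic folder can be swapped in by assigning any
callable with the `fold_mfe` signature wherever a folder is taken.

Consequence of the simplification: absolute MFE values are not
comparable to full Turner-parameter folders to better than a few
kcal/mol, but the discrimination that matters here — long complementary
stems fold strongly negative, random sequence does not — is preserved,
and the MFE acceptance threshold was calibrated on the same scale.

## Novel miRNA discovery

Candidate tags are unannotated, 20–24 nt, with ≥ 5 reads over both
libraries (a conventional minimum-abundance floor for hairpin
screening). Their perfect hits are clustered into loci (same record and
strand, footprints within 30 nt — enough to bridge the hairpin loop, so
a mature, its processing variants and its star share one locus). Only
the most abundant tag of each locus (the presumptive mature product) is
evaluated; this mirrors how dedicated discovery tools treat isomiR
clouds and prevents one hairpin from yielding a dozen shifted
"discoveries".

For each locus two windows are excised (tag near the 5′ end with a 160-nt
downstream flank, and the mirror), bounded to 60–300 nt. Before folding,
a window must contain a plausible antisense partner for the mature
(≤ 6 unpaired bases, wobbles allowed) outside the mature's own footprint;
windows without one cannot satisfy the duplex criterion and are skipped.
A folded candidate is accepted iff, in order:

1. the mature lies on one arm (no self-pairing, all partners on one
   side, ≤ 2 nt protruding past the innermost stem pair into the loop);
2. ≤ 4 mature bases are unpaired in the duplex and no internal loop in
   the duplex is asymmetric by > 2 nt;
3. the miRNA\* — the duplex partner computed from the pair table with
   2-nt 3′ overhangs — is observed among the sequenced tags with ≥ 1
   read. The star's 5′ end may deviate by ≤ 2 nt from the computed
   position: flanking sequence can shift the optimal fold by a base or
   two at the duplex ends, and processing itself is not perfectly
   precise, so demanding byte-exact star boundaries would discard
   genuine loci;
4. MFE ≤ −18 kcal/mol — the weakest precursor accepted in comparable
   plant studies; configurable.

Rejections carry the first failed criterion. Identical matures from
several loci merge into one entry with a loci count; serial names are
assigned by descending total mature abundance, ties broken
lexicographically.

## Differential expression

Normalized expression = count / library total × 10⁶ (reads per million).
The denominator defaults to the library's total clean reads, which
reproduces the bundled study's normalized columns; it is configurable
because some studies normalize by total miRNA reads instead. Zero
normalized values become 0.001 so condition-specific miRNAs keep finite
fold changes; fold change = log₂(stressed/control).

Significance is the exact Audic–Claverie test: given count x at depth N₁
and r = N₂/N₁, the conditional distribution of the second count is

    P(y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),

the negative binomial NB(x+1, 1/(1+r)), evaluated in log space through
scipy. The two-sided p doubles the smaller of the complementary tails
P(Y ≤ y) and P(Y > y), capped at 1; using complementary tails makes the
statistic exactly symmetric under swapping the libraries and gives
p = 1 for identical observations at equal depth. Calibration is tested
empirically (type-I error at α = 0.05 within [0.03, 0.07] over 2,000
seeded null pairs).

Regulation: up iff linear ratio > 2 and p ≤ 0.05; down iff ratio < 0.5
and p ≤ 0.05 (equivalently |log₂fc| > 1). No multiple-testing correction
is applied by default — single-library-per-condition designs rarely do —
but a Benjamini–Hochberg flag is available.

## Degradome target calling

Degradome tags are 20–21 nt reads (mean Phred ≥ 20 when qualities are
present) collapsed to counts and mapped to transcripts by perfect
sense-strand match; a multi-site tag contributes its count at every
site, and the total mapped count normalizes t-plots to TP100M
(raw × 10⁸ / total mapped).

miRNA:transcript duplexes are scored over every ungapped antisense
window: mismatch 1.0, G:U 0.5, penalties doubled at miRNA positions
2–13; gapped alignment is not scanned (the 2.0 gap constant is reserved
for parity with the published scoring convention). An alignment is kept
when score ≤ 4.0 (the largest score observed in the reference study's
reported targets), full mismatches ≤ 5, and miRNA positions 10 and 11
are strict Watson–Crick (wobble disallowed at the cleavage site). The
reported cleavage site is the transcript base opposite miRNA position 10
— exactly where slicing leaves the 5′ end of the 3′ fragment.

Categories, computed on the raw per-position profile:
I — the site equals the transcript maximum, that maximum is unique, and
the site has > 1 raw read; II — > 1 raw read and above the median of
occupied positions (covers tied maxima); III — any remaining supported
site. The median is taken over positions with ≥ 1 read; zero-abundance
sites yield no call.

## Synthetic data generator

Defaults describe a desk-scale version of a two-library plant study:
20 transcripts of 0.5–3 kb, 12 planted hairpin loci (stem = mature +
reverse complement with 0–2 substitutions, 8–15 nt loop, alternating
5p/3p arms), 2×10⁵ reads per library, 5×10⁴ degradome reads. Expected
mature abundances are drawn once per study from 100–1500 reads (quoted
at a fixed reference depth of 2×10⁵ so per-read species probabilities
are depth-independent), with fold classes cycling through 4×-up,
4×-down and unchanged; star abundance is 5 % of the mature with a floor
of 6 expected reads. Libraries are multinomial draws mixing planted
species, a small set of synthetic "known" miRNA families, ncRNA
fragments (rRNA 10 %, tRNA 5 %, snRNA 1 %, snoRNA 1 %) and random
degradation fragments with the 21/24-nt-peaked length profile typical
of plant libraries. Degradome signatures start exactly at the base
opposite miRNA position 10 of planted perfect antisense sites; by
default background 5′ ends avoid target transcripts so planted sites
are their transcripts' unique maxima (category I by construction).
Identical configs produce byte-identical files.

Deliberately not emulated: sequencing errors and quality decay
(qualities are constant 'I'; quality filtering is exercised by dedicated
fixtures), genomic repeats and multi-mapping ambiguity, realistic
expression dispersion between biological replicates, and
genome-scale references. Passing the recovery tests therefore shows the
algorithms are correct under clean, known-truth conditions — not that
the pipeline is robust to every artefact of real sequencing data.

## Numerical and procedural choices

* All tie-breaks (member assignment, novel-miRNA naming, call ordering)
  are lexicographic/deterministic; reruns are byte-identical.
* Fold-change and ratio reports round to 2 decimals, normalized
  abundances to 4 — matching the precision such studies print.
* Degenerate inputs: empty read streams yield empty outputs with zeroed
  tallies; an empty reference leaves all tags unmapped; folding a
  pair-free sequence returns the open structure with MFE 0.
* Problem sizes in the test suite: the folding oracle enumerates all
  nested structures for 500 seeded sequences of ≤ 14 nt; end-to-end
  recovery runs the full default-scale synthetic study plus a
  hairpin-free control.

## Limitations

* The energy model is a teaching-grade approximation; for
  publication-grade precursor energies, swap in a full thermodynamic
  folder and recalibrate the MFE threshold.
* Known-miRNA assignment is ungapped; indel isoforms are not assigned.
* Degradome alignment is ungapped (consistent with the score-≤-4 regime,
  where a 2-point gap plus doubling leaves little room).
* One library per condition: the count test measures sampling
  variability only, not biological variance between replicates.
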