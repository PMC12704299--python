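# Methods

`ampedit` quantifies CRISPR editing outcomes at a single amplicon from deep
sequencing reads, and predicts where and how a nuclease will cut before any
sequencing is done. This note documents the models, conventions, defaults
and known limitations; the README shows a worked run.

## Cut-site model

A nuclease chemistry is described by its PAM motif (IUPAC), the side of the
protospacer the PAM occupies, and its cut geometry:

* **SpCas9** — 3' NGG PAM, blunt cut placed 3 nt 5' of the PAM (between
  protospacer positions 17 and 18 of a 20-mer counted from the PAM-distal
  end). The cut window is a single gap coordinate.
* **AsCas12a** — 5' TTTV PAM, staggered cut with offsets 18 and 23 nt from
  the PAM-proximal protospacer end, leaving a 5-nt 5' overhang. The cut
  window spans both strand cuts.

Both offsets are configurable per profile; the presets encode the canonical
geometries. Guide placement requires an exact spacer match (mismatched
binding is the off-target scanner's job), and an ambiguous reference base
(N) never matches a spacer base; in a PAM position it satisfies only the
pattern code N. Coordinates are 0-based half-open internally, with cut
windows as inclusive pairs of gap coordinates (positions between bases);
reports emit 1-based inclusive coordinates.

## Microhomology and MMEJ

Microhomology-mediated end joining anneals two identical direct repeats
flanking the break and deletes one copy plus the intervening bases. The
enumerator reports every *maximal* identical substring pair straddling the
cut window: the left copy may end anywhere up to the window's right edge
and at most `search_window` nt (default 30) left of it, the right copy
starts at or after the window's left edge and at most `search_window` nt
right of it; copies must not overlap each other. Maximality is defined by
joint sequence extension — growing both copies one base in either direction
breaks the identity — so tandem or homopolymer runs whose maximal copies
would overlap are excluded. The default minimum length of 2 nt is the
smallest repeat that distinguishes an MMEJ-style junction from a blunt
join; deletions implied by longer repeats rank first.

For an **observed** deletion, the junction-microhomology statistic counts
the alternative placements of the same deletion product: the deletion is
slid left and right while the product is unchanged, and `mh_len` is the
total slide range (0 for a clean blunt join). This is placement-invariant,
so it does not matter where the aligner or the caller put the gap inside a
repeat.

## Alignment and indel calling

Reads are aligned end-to-end (global affine-gap Needleman-Wunsch/Gotoh, via
Biopython's `PairwiseAligner`) with match +2, mismatch -2, gap open -6 and
gap extend -1. The opening penalty is charged on the first gapped base, so
a gap of length L costs `6 + (L - 1)`; with these scores one 8-nt deletion
(cost 13) beats scattering the same length difference across several short
gaps, which matches the single-deletion structure of nuclease alleles.
Contiguous gap runs become single events; substitutions are recorded but
never merged into gaps. Every indel is then left-normalized (shifted to the
smallest reference coordinate preserving the read sequence, without
crossing another event), so all reads carrying one allele produce identical
event lists regardless of traceback arbitrariness.

Paired 2x150 reads are merged first by their best ungapped 3' overlap
(minimum 20 nt, at most 10% disagreement; higher-quality base wins at
conflicts). Reads shorter than 50 nt are discarded, and reads aligning at
below 60% identity are set aside as unassigned and excluded from every
denominator, so contaminant reads cannot inflate the WT fraction. All of
these thresholds are exposed as parameters; the numbers are package
defaults chosen for ~200-nt amplicons.

## Outcome taxonomy

Reads collapse to alleles by a canonical key over their indel events
(substitutions do not define alleles). Categories, in precedence order:

1. **wt_or_sub** — no indel (substitution-only reads count as unedited);
2. **insertion** — any insertion event, regardless of position (mixed
   insertion+deletion alleles land here; a separate "complex" category can
   be added by callers that need it);
3. **deletion_on_position** — a deletion whose ambiguity-expanded interval
   (union of all equivalent placements, padded by `pad`, default 1 nt)
   intersects the cut window; flagged **MMEJ** when its junction
   microhomology is at least `min_mh` (default 2 nt);
4. **deletion_off_position** — all remaining deletions.

The ambiguity expansion matters: a repeat-mediated deletion called at its
left-normalized placement may sit entirely left of the cut, yet one of its
equivalent placements spans it. Editing efficiency is `1 - WT fraction`;
category fractions are computed with exact rational arithmetic before the
final float conversion and always sum to 1. Arm comparisons report
per-category differences with Wilson 95% intervals and a pooled
two-proportion z statistic.

## Off-target scanning

The scanner follows the Cas-OFFinder convention: the PAM must match its
IUPAC pattern exactly, mismatches are counted over the protospacer only
(Hamming; no bulges), and a configurable budget (default 4) bounds them.
N in the database matches nothing, including in the PAM — a deliberately
conservative choice that differs from on-target PAM matching, where N may
satisfy pattern code N. Exon intervals take precedence over gene bodies
when annotating hits (exonic > intronic > intergenic); BED input is taken
as 0-based half-open and GFF3 as 1-based inclusive, converted on read, with
the dialect logged. Genome-scale scans work but are not what the tests
exercise: genome-wide exonic hit counts depend on the genome build and
annotation version, so the suite uses synthetic mini-genomes with planted
sites.

## Synthetic data

The generator emulates MiSeq amplicon sequencing: each read is one edited
amplicon molecule drawn i.i.d. from an allele spectrum, with substitution
errors applied independently per base (error rate default 0.001, typical of
a Q30 run; quality strings are constant Q30). Paired mode emits 150-nt
reads from the fragment ends with the second read reverse-complemented;
fragments shorter than a read are truncated and flagged. The default depth
is 20,000 reads per arm.

Spectra are built from category-level fixtures. The two packaged fixtures
encode the two study arms at the TCR-beta constant-region consensus
amplicon: the AsCas12a/CRAFT-crRNA arm (WT 4.6%, insertion 0.1%,
on-position deletion 90.6% of which 11.0 points are MMEJ-repaired,
off-position deletion 4.6%; categories sum to 99.9% as printed and are
renormalized on load) and the SpCas9/sgRNA arm (WT 35.4%, insertion 4.0%,
on-position 44.7%, off-position 15.9%, no MMEJ). Expansion into concrete
alleles draws MMEJ deletions from the enumerated microhomology products and
samples non-MMEJ on-position deletions (1-20 nt overlapping the window,
junction microhomology below `min_mh`), insertions (1-10 random nt at the
cut) and distal deletions (at least `pad`+5 nt from the window); every
sampled allele is verified against the classifier, so truth labels and
taxonomy agree by construction. The generator writes FASTQ plus a per-read
truth table and is byte-reproducible from its seed.

What the simulation does **not** model: sequencing indel errors (they would
confound the indel taxonomy under test), PCR chimeras and jackpots,
per-cycle quality decay, and large structural variants extending beyond the
amplicon. Recovery results on simulated reads therefore demonstrate that
the analysis inverts the generative model faithfully, not that real
libraries are free of those artifacts.

## Numerical and design choices

* Alignment traceback arbitrariness is neutralized by left-normalization
  rather than by prescribing a traceback order; only normalized events are
  compared or keyed.
* Ties in allele ranking break lexicographically on the allele key; floats
  in reports carry 4 decimals and percentages use the 0-100 scale, making
  reruns byte-identical.
* The recovery experiments spawn independent child seeds for spectrum
  construction and read simulation from the one user seed
  (`numpy.random.SeedSequence`), so the stages are decoupled but fully
  reproducible.
* Experiment sizing (20,000 reads per arm, amplicon-scale references in
  property tests, 5-kb synthetic genomes for the off-target oracle) keeps
  every run deterministic and fast while leaving multinomial noise at
  20,000 reads an order of magnitude below the recovery tolerances.
* Degenerate inputs fail loudly: empty references, out-of-bounds cut
  windows or deletions, ambiguous guide bases, overlapping allele events
  and unreadable FASTQs all raise with the offending coordinate or file
  named.

## Known limitations

* Only exact, ungapped microhomologies are enumerated; mismatch-tolerant
  ("degenerate") microhomology and resection modelling are out of scope.
* The off-target scanner does not score or rank hits by cleavage
  likelihood, and DNA/RNA bulges are not searched.
* Guide efficiency prediction, chromatin accessibility weighting and
  translation of alleles to protein consequences are out of scope.
* Adapter trimming is assumed to have happened upstream.
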