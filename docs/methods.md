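# Methods

## The problem

musekit implements a complete in-silico framework for communicating short
messages in DNA in three stages: a keyboard-shaped substitution cipher that
writes plaintext as codons while bounding homopolymer runs (iKey-64), a
secret-sharing scheme that fragments a message and a decoy across several
DNA molecules (MuSE, Multiplexed Sequence Encoding), and a data-extraction
route in which the molecules are co-sequenced in a single Sanger reaction
and the shared message regions appear as a pattern of large homogeneous
peaks separated by heterogeneous troughs.

## The iKey-64 cipher

The 4-letter DNA alphabet gives 4³ = 64 three-base codons, which partition
structurally into:

* **CAT1** (24 codons) — all three bases distinct;
* **CAT2** (12) — first and third base equal, middle different;
* **CAT3** (28) — at least one adjacent repeated base.

Buttons are allocated to categories by usage frequency: all ten digits,
both word spacers (space1 = AGT, space2 = CTA) and the twelve most frequent
letters take CAT1 codons; the next twelve letters take CAT2; the rarest
characters, punctuation, and function keys take CAT3, with the four fully
homopolymeric codons AAA/CCC/GGG/TTT reserved for function keys.  Because
no non-function codon contains a three-base run, any two adjacent
non-function codons contribute at most 2 + 2 = 4 equal bases at a
junction, and any two CAT1 codons at most 1 + 1 = 2.  Both bounds are
verified exhaustively in the test suite (3600 ordered codon pairs; 100
digit pairs).

Shuffling codons within categories preserves the allocation and yields
24!·12!·28! ≈ 9.1×10⁶¹ keyboard variants (64! ≈ 1.3×10⁸⁹ without the
category constraint); `randomize_ikey` performs this shuffle with a seeded
`random.Random`.  A keyboard serializes to DNA as its 64 codons in button
order flanked by 10 T on each side (212 nt total), and parses back given
the ordered button labels.

### Reference-layout reconstruction

The physical keyboard figure in the source work does not print the full
button-to-character map, so the shipped reference keyboard is a documented
reconstruction pinned to every printed constraint: button order equals the
codon order of the printed 212-nt record; digits 1–9,0 occupy buttons 2–11
(consistent with '1' = AGC at triplet 2 and '0' = CTG at triplet 11);
'v' = GTT, 'k' = TTC, space1 = AGT, space2 = CTA.  Free choices, made once
and fixed:

* AAA = start, CCC = shift, GGG = end, TTT = forward; `reverse` takes the
  first free CAT3 codon (the record's first triplet, CGG).  Five function
  labels compete for four homopolymeric codons; start/end/shift are used by
  the codec itself, and forward was kept on a homopolymer ahead of reverse
  arbitrarily.
* Remaining letters fill their category's free codons in record order by
  descending Concise-Oxford letter frequency (ties keep table order).
* 21 punctuation characters (`.,:;!?'"-&()/@#$%+=*_`) fill the leftover
  CAT3 codons.

All operations take the keyboard as data, so none of these choices is
load-bearing; the layout ships both as code (`build_reference_ikey`) and as
a TSV fixture (`musekit/data/ikey64_reference.tsv`), with a test asserting
they agree and that serialization reproduces the printed record exactly.

Decoding emits lowercase; a shift codon uppercases exactly the next
character button, two consecutive shifts are an error (no caps-lock
semantics), and both spacers decode to a single space.  Non-spacer function
buttons decode to `<label>` tokens; decoding them never flips a strand.

## MuSE composition

A communication holds a message *m*, a decoy *d*, a keyboard *k*, one
watermark codon per strand, and a combination key.  With N strands
(N ∈ {2, 4, 6}) the message is split on word boundaries into N/2 near-equal
fragments (remainder to earlier fragments) shared by consecutive pairs
(n1+n2, n3+n4, …); the decoy fragments are shared by the circularly
shifted pairs (n2+n3, …, nN+n1).  Each strand carries, on one information
orientation:

    [ExternalFw site][leading filler][Primer_Key site][watermark codon]
    [combination key][Primer_Message site][message slot][decoy slot]
    [trailing filler][rc(ExternalRv site)]

Every region has the same length on every strand (slots are padded with
per-strand random filler after the end codon), so arbitrary template mixes
stay base-aligned over the entire read.  Odd strands use space1 and even
strands space2 as the word separator, making pair partners identical inside
words and different at exactly the three spacer positions.  Even strands
are stored as the reverse complement of their layout — the orientation
camouflage — and the printed constructs confirm the convention: the key
primer sits forward on n1/n3/n5 and reverse-complemented at the 3′ end of
n2/n4/n6.

Watermarks are the six permutations of AGC, ordered so odd strands carry
AGC/GAC/ACG as observed at positions 127–129 of the printed n1/n3/n5;
this caps the composer at six strands, the largest communication
demonstrated.  The combination key text (default
`Pascal's triangle: d2r6-reverse`) resolves by enumerating diagonal 2 of
Pascal's triangle down to row 6 — the counting numbers 1…6 — and pairing
consecutive entries; the grammar accepts `pascal:d<k>r<n>-<direction>` and
the spelled-out riddle.  The direction field is carried for primer choice
and not otherwise interpreted.

Filler ("variable DNA") is seeded uniform random with homopolymer runs
capped at 2.  The `camouflage` filler policy splices a 6-base C or A run
(alternating by strand parity) into the *leading* filler only, mirroring
the 5′ homopolymer stretches that defeat forward co-sequencing while
leaving message-side reads clean.

The printed WWII constructs (n1–n6) are consumed read-only: their exact
internal coordinates and the original authors' keyboard layout are not
reconstructable from print, so tests assert their structural invariants
(lengths, primer sites, watermark positions, block patterns) rather than
regenerating them bit-exactly.

## Co-sequencing simulation

Each template in which the common primer has exactly one exact-match site
(searched on both orientations; mismatched annealing is out of scope)
contributes its normalized concentration to the channel of its base at
every read position.  Intensities are exact fractions — the patterning
claims being modelled are structural, not photometric — with optional
seeded Gaussian channel noise behind a flag.  The base call is the argmax
channel with a fixed A<C<G<T tie-break; a position is *homogeneous* when
the top channel's share is at least the purity threshold (default 0.9,
configurable), else *heterogeneous*.  At a two-template mismatch the
minor-peak share is min(r, 1−r) under this linear mixing model, which is a
stated assumption: the relationship between molar ratio and physical peak
height in real chromatograms is not calibrated here.

**Dephasing.**  Real mixed reactions lose base-call register when long
homopolymers sit in non-identical regions.  The model is a hard transition:
at the first position where participating reads disagree and any read
contains a homopolymer run ≥ `min_run` within a `window`-long lookahead
(defaults 5 and 10), every downstream position becomes *unreliable* and is
called N.  `min_run` = 5 because legitimately encoded text reaches runs of
3–4 (homopolymeric function codons; CAT3 junctions such as GTT+TTC) that
must not break a trace, while camouflage filler injects runs of 6.  The
simulator default is dephasing off; pass a `DephasingPolicy` to enable it.

Defaults: read length 700 nt (typical usable Sanger read), purity 0.9.

## Pattern decoding

`detect_blocks` takes maximal same-class runs and merges homogeneous runs
shorter than `min_block` (default 9 nt = 3 codons, suppressing chance
matches in filler) into their neighbours.  `decode_framed_regions` finds
the codon frame by scanning all three offsets for a fully homogeneous start
codon, then walks codon-by-codon: a fully homogeneous codon decodes (or
terminates the frame at the end codon); a codon containing any
heterogeneous position is a single-codon gap emitted as a word separator;
two consecutive gap codons abort the attempt, so only regions bounded by
decodable blocks survive.  A gap whose channels show more than two distinct
bases in a column cannot be a two-strand spacer (three or more templates
disagree) and is emitted as a `<wm>` watermark placeholder instead of a
space.  An undecodable trace yields an empty report, never an exception.

`compare_sequences` is the sequence-space oracle: a positionwise
match/mismatch decomposition of two strands co-aligned 3′ of a unique
anchor, with the same short-run merging; on noiseless traces it must and
does agree with `detect_blocks` exactly.  Sequence-space extraction
(`extract_communication`) and trace-space decoding (`decode_pattern`) are
two independent routes through the same framed-decoding core.

With two strands the circularly shifted plan names the same unordered pair
as the message plan, so one trace carries two framed regions; the fixed
slot order (message before decoy) plus the plan's role selects the first or
last frame.

## What the composed data does and does not emulate

Composed strands reproduce the structural features the method depends on —
shared primer sites, aligned equal-length regions, spacer parity,
watermarks, orientation flips, homopolymer-bounded fillers — under
noiseless, perfectly registered reads.  They do not emulate mobility
shifts, dye blobs, basecaller behaviour, synthesis errors, or the 5′/3′
quality falloff of real traces, and the dephasing transition is an
idealized cliff rather than a gradual register walk.  Passing tests
therefore demonstrate the logic of encoding, sharing, and pattern
extraction, not robustness to instrument noise.

## Problem sizes

The test suite and the acceptance checks run entirely at desk scale:
exhaustive codon-pair scans (≤ 3600 pairs), the printed constructs
(≤ 525 nt), and 50 seeded random communications of 2–6 strands with reads
of a few hundred positions.  The whole suite completes in a few seconds.

## Known limitations

* The composer caps at six strands (distinct watermark permutations of one
  CAT1 codon) and pairwise sharing; threshold k-of-n schemes are out of
  scope.
* Primer annealing is exact-match only; no mismatch tolerance.
* Decoded text from the printed WWII constructs is unavailable by design —
  it requires the original authors' keyboard layout, which print does not
  determine; the demo reports their block structure and decodes a freshly
  composed communication instead.
* No data compression before encoding, and no cryptographic layer; the
  cipher is a substitution keyed by the keyboard layout.
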