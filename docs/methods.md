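# Methods

## Scope and model of the data

One record couples 21 standardised metadata fields with up to three
abundance blocks keyed by taxon code: the original values as published
(mapped onto the master taxonomy only), corrected absolute counts (for
raw-count sources) and corrected relative proportions (always present for
retained records). Values are tri-state: a non-negative number, an explicit
zero, or *not available* (`None` in memory, an empty cell on disk). The
NA/zero distinction is load-bearing everywhere: NA means a study carried no
information about a category, never that the category was absent.

The master taxonomy comprises 47 species categories (six of which have never
been recorded in the analysed size fraction but are kept so output columns
are stable), 3 multi-species (lumped) categories, 6 morphotype categories
whose counts are already contained in their parent species, one
`unidentified` sink, and a set of *legacy* categories (P/D intergrades,
*G. flexuosa*, *G. crassula*, "other identified", *G. puncticulata*) that
exist only to receive historical labels before dataset-specific merge rules
fold them into master categories. Morphotypes never enter sums, totals,
normalisation or similarity; they are rescaled alongside their parents so
the blocks stay internally consistent.

## Key procedures and their parameters

| parameter | default | meaning |
|---|---|---|
| sum deviation | 0.05 | tolerated \|Σ−1\| of relative categories before exclusion |
| minimum count | 150 | individuals; fewer excludes the sample |
| max unidentified | 0.05 | tolerated proportion of unidentified specimens |
| endemic threshold | 0.01 | out-of-range endemic abundance that excludes; traces at or below are folded into `unidentified` |
| rounding unit | 0.001 | assumed rounding of individual published categories |
| category deviation | 0.01 | duplicate criterion on per-category relative abundances |
| total deviation | 0.03 | duplicate criterion on counted totals, relative to the pair mean |
| plain distance | 2.621 km | same-name duplicate distance ceiling |
| different-name distance | 0.5242 km | different-name duplicate distance ceiling |
| repair displacement | 3.7 km | minimum move for a credible minutes-as-decimals repair |

All exclusion comparisons are strict as printed in the protocol ("below
150", ">5%", ">1%", "more than 5%"); an abundance of exactly 1% in an
out-of-range endemic species is folded into `unidentified` rather than
flagged. A record is retained iff its Error flag is ≤ 1, i.e. at worst
"modified"; bits accumulate by OR, so the exclusion set is independent of
filter order (verified by a permutation test). The outlier and dissolution
bits exist in the flag scheme but no filter sets them — deliberately out of
scope, mirroring the curation protocol.

Geodesy uses the haversine formula on a sphere of radius 6371.0 km. That
radius is not a free choice: it reproduces the protocol's own worked
thresholds (2.621 km for the 0.5′ equatorial pair, 0.5242 km for the 0.1′
pair) to four significant figures, which an ellipsoid does not. The
minutes-as-decimals repair maps D + f to D + (100·f)/60, is valid only when
100·f < 60, extracts the fractional part after rounding at six decimals to
avoid phantom minutes from binary floats, and is the exact inverse of the
corruption the synthetic generator injects. Repair combinations over a
sample pair touch at most two of the four coordinates; a combination is
accepted only if it moves a member by more than 3.7 km (the literal
threshold, not recomputed from the 5′ gloss it approximates) *and* brings
the pair inside the plain-duplicate distance. When no repair is credible, a
pluggable bathymetry provider arbitrates by best agreement between stated
water depth and seafloor depth; with no provider the oldest publication's
position is kept and the case is logged unresolved.

Ocean basins feed two things: the Ocean flag and the endemism dichotomy
(Atlantic + Mediterranean versus Pacific + Indian + Red Sea). Basin lookup
is a provider interface; the shipped fallback uses coarse latitude/longitude
boxes that are adequate for the dichotomy and for hemispheric subsetting but
are *not* shoreline-accurate, and marginal seas do not set their parent
basin's bit. A gridded mask provider can replace it with richer semantics.

Merging a duplicate cluster maximises information: the member with the most
numerically known non-morphotype categories donates the assemblage; position
precedence is highest recorded precision (number of printed decimal places,
which is tracked from ingestion through serialisation); sediment-depth
metadata prefers complete upper/lower bounds over an average alone; all
other fields prefer presence over absence, with conflicts resolved in favour
of the older publication. Ties (equal category counts, equal precision,
equal year, missing years — treated as newest) fall back to the
lexicographically smaller sample id, making detection and merging invariant
under permutation of the input. The Database flag of a merged record is the
bitwise OR over members, so constituent compilations remain reconstructable.

## Determinism, audit and recoverability

The pipeline contains no randomness; identical configurations give
byte-identical outputs, which is how "replayability" is guaranteed and
tested. Every value-altering operation sets the `modified` bit, appends to
the record's comment, and writes a structured audit entry (sample, stage,
target, before, after); excluded and merged-away records stay in the full
export. The audit trail is evidence for tracing, not an executable redo log:
reproduction is by rerunning the deterministic pipeline rather than by
replaying entries.

Serialisation writes relative values in shortest-repr form (lossless,
exceeding the 0.1% granularity the data carry) rather than at a fixed six
decimals, precisely so that read∘write is the identity; coordinates are
written at their recorded precision.

## What the synthetic corpus does and does not emulate

The generator draws base assemblages from a symmetric Dirichlet
(concentration 0.3 over the 41 recordable species), which mimics the skewed
dominance structure of real assemblages; the four endemics are zeroed in
clean samples so planted endemism violations are unambiguous. Positions are
minute-aligned (as ship positions usually are) and recorded at four
decimals. Clones planted across datasets carry the corruptions seen in real
compilations: rounding to 0.1%, totals jittered within ±2% (inside the 3%
criterion), punctuation name mutations for different-name duplicates,
latitude minutes-as-decimals corruption (only where the repair is
recoverable and displaces >3.7 km) for incorrect-position duplicates, and
sub-threshold position jitter for plain duplicates. QC violations (one per
filter kind) and negative controls (same-site recounts deviating ≥2× the
faunal criterion; faunally identical "far twins" ≥2× beyond every distance
ceiling) are planted alongside, and every plant is validated against the
pipeline's own similarity predicate at generation time and recorded in a
truth ledger. Defaults — five datasets of 200 samples with 15% overlap —
are the study conditions the acceptance suite runs under.

The generator does *not* emulate species–environment coupling, real
biogeography, dissolution gradients, or adversarial corruption outside the
planted classes. Passing tests therefore demonstrate that the machinery
detects exactly what its criteria define — within-threshold clones are
always found, beyond-threshold controls never merged — not that those
criteria are ecologically optimal for any particular real archive; samples
like technical replicates with genuinely divergent recounts are by design
retained, not merged.

## Degenerate inputs and edge rules

Empty or non-numeric abundance cells become NA with a warning; unparseable
or out-of-range coordinates are kept missing and later flagged rather than
dropped. A lower sediment depth of exactly zero is moved to the upper bound.
A missing `Count_min` defaults to the 300-individual counting standard, and
the low-count filter falls back on `Count_min` only when no actual count
exists, so the default can never trigger it. Zero-sum relative vectors are
flagged as sum-deviant. Pairs sharing no numerically known category fail
similarity outright; the total-count criterion is vacuous when either total
is unknown. Unknown taxon labels resolve to a sentinel and are reported,
never guessed; `Mini` corers count as a standard device (the device filter
whitelists them), while missing devices are flagged — conservative but
configurable.
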