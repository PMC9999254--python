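# Methods

## The labeling problem

A hospital stay is a HAPI case when a pressure injury is newly developed or
worsened between admission and discharge. The engine labels each stay
independently (multiple stays per patient are never merged) from four EHR
sources: timed PI staging chart events, free-text notes, untimed ICD-9
diagnosis codes and procedure codes. Every stay ends up in exactly one of
three states — case, control or excluded — and every case carries the
evidence route that fired and, for timed routes, an event timestamp.

## Stage encodings

Staging chart values are normalised to six tokens: numeric stages 1–4, deep
tissue injury (DTI) and unstageable. The admission and discharge encodings
are deliberately asymmetric:

| token       | admission | discharge |
|-------------|-----------|-----------|
| stage 1–4   | 1–4       | 1–4       |
| DTI         | 4         | 3         |
| unstageable | 0         | 5         |
| absent      | 0         | —         |

DTI is a stage-3-or-4 injury without a visible stage; coding it 4 at
admission and 3 at discharge means a DTI documented at both ends registers
as an improvement and is excluded when only new/worsened PIs qualify.
Unstageable is 0 at admission (it cannot rule a PI *in* as pre-existing)
and 5 at discharge (it always captures a possible HAPI). Absent admission
staging is 0: no documentation means no documented admission PI.

Choices the source descriptions leave open, fixed here:

* The admission stage aggregates by **max** over the window — the worst
  documented stage, consistent with present-on-admission coding practice.
* "Last recorded stage above 2" is read **≥ 2**: the minimum-stage
  dimension is 2 for two of the four policies, which a strict reading would
  contradict.
* Ties at an identical discharge timestamp resolve to the max encoded
  value, making the result order-independent.
* The minimum-stage filter applies to the *encoded discharge value*, so
  unstageable (5) and DTI (3) always qualify where they are enabled at all;
  where a policy disables them (D5 = no) the tokens are removed before any
  staging computation.
* Only numeric stages 1–4 inside the admission window trigger the
  "PI documented on admission" exclusion. Admission DTI and unstageable
  events flow into the deterioration logic instead — otherwise the
  admission encodings above would be dead code, and an unstageable PI on
  admission that is later staged could never count as hospital-acquired.

## The four policies

| dimension | EHAPI | CANTRIP | Cramer | Sotoodeh |
|---|---|---|---|---|
| D1 exclude deceased | yes | no | no | no |
| D2 min age (years)  | 15 | 15 | 18 | 18 |
| D3 admission window | 24 h | 48 h | 24 h | n/a |
| D4 min stage        | 2 | 1 | 2 | n/a |
| D5 DTI/unstageable  | yes | yes | no | n/a |
| D6 note keywords    | yes | yes | no | yes |
| D7 new/worsened only| yes | no | no | no |
| D8 ICD-9 codes      | no | no | no | yes |

Common inclusion for all four: at least one clinical note, discharge after
admission, the age minimum, and no PI documented on admission. The
note-based admission screen always uses 24 h regardless of D3. CANTRIP's
keyword route requires time-stamped notes and strictly more than 48 h from
admission (both its windows follow its date-of-event definition). Sotoodeh
has no staging timeline; its admission screen is the 24-h note screen only
(ICD-9 codes are untimed and cannot be placed at admission), and its
keyword route uses the same 24 h boundary — a mention at or before 24 h
excludes the stay anyway, so no earlier mention could have been a case.

## Note scanning and negation

Phrase matching is case-insensitive with word boundaries (so "decubitus"
never fires inside a longer word), longest phrase first, non-overlapping.
A mention is negated when a trigger ("no", "without", "denies", …) ends
within five tokens before it inside the same sentence (boundaries: `.!?`
or newline), or a structured dismissal ("bedsore: none") follows it. This
is a trigger-window scheme in the NegEx tradition; contextual or ML
negation is out of scope. The default phrase and trigger lists are a
faithful but configurable emulation — analyses on a real export should
install the site's own lexicon, and counts on real data are
lexicon-dependent.

Date-only notes (a real feature of MIMIC note data) are assigned their date
at 00:00 and flagged. The 00:00 stamp under-approximates the true charting
time, so for the strict "later than cutoff" comparisons it can only miss a
borderline mention, never invent one; policies that require time-stamped
notes skip flagged notes entirely. Ages above 120 years (obfuscated dates
of birth) clamp to a configurable 90-year cap.

## Congruence analytics

Source indications ignore timing and eligibility entirely — a stay appears
when any source shows any PI evidence — so the analysis runs on all stays.
UpSet counts are an exact partition: each stay contributes to exactly the
combination equal to its full source set, so combination counts sum to the
union and per-source totals equal the sum over combinations containing the
source. The same tabulation applied to per-definition case sets gives the
definition-overlap view; the all-definitions cell is the consensus case
set.

## The benchmark

The benchmark asks whether a notes-only classifier can recover a
definition's labels *without being shown the answer*. Two leakage channels
are closed:

1. **Temporal**: each stay gets an event timestamp and only notes strictly
   before it form the document. Evidence stays use their earliest timed PI
   evidence later than 24 h after admission. Timestamps are
   definition-agnostic because all definitions share one feature set.
2. **Lexical**: every lexicon phrase occurrence is scrubbed from every
   document and a hard assertion re-checks the invariant on every run.

Stays without timed PI evidence would otherwise contribute arbitrarily long
note histories, letting a classifier learn "long history ⇒ control". Their
timestamps are therefore sampled: the case note durations (event timestamp
minus earliest note) are fitted by maximum likelihood in four candidate
families — exponential, gamma, log-normal, Weibull — scored by Pearson
chi-square on 20 equal-probability bins, smallest score wins. Because the
exponential is nested inside gamma and Weibull, a raw score comparison
would let an extra shape parameter win on binning noise alone; selection
therefore charges each family the 95% chi-square quantile per fitted
parameter beyond the leanest candidate before comparing. Even so, a
near-exponential gamma or Weibull fit is *statistically indistinguishable*
from the exponential at these sample sizes, and which label wins can vary
with the sample; the fitted distributions, and hence the sampled
timestamps, are essentially identical either way. Fewer than 20 durations
(or a constant sample) fall back to the empirical distribution, flagged.
One duration is drawn per control, sampled and true durations pair by rank,
each control's offset is the min of its pair (so no control's window
exceeds what its notes actually span), and timestamps cap at discharge.
The control "true duration" is last-note minus first-note time.

Test sets share all consensus cases and all annotated disagreement stays
and differ only in the random subsample of consensus controls; per
definition, the training set is that definition's eligible stays outside
the pooled test stays, labeled by that definition. Annotations are an
input file in real use; for synthetic cohorts a helper derives stand-in
annotations from the generator's ground truth, covering a minority of
disagreement stays so that definition-specific cases remain for training.

Features are TF-IDF vectors (top-5000 training vocabulary, smoothed idf,
L2 norm) for gradient boosting, and 800-token index sequences (pad and OOV
reserved) for the sequence model: a learned embedding (dim 64), global max
pooling and two dense layers with a sigmoid output, trained with mini-batch
Adam on binary cross-entropy — a compact numpy implementation, deterministic
given its seed. Hyperparameters come from 5-fold cross-validation on the
training split maximising average precision (AUPRC); equal-probability
binning and the CV objective are config-exposed. Metrics are AUPRC and
AUROC per test set; definition comparisons use a one-sided paired t-test
across test sets, with degenerate zero-variance differences flagged
(all-zero → p = 0.5; constant non-zero → p = 0 or 1).

## Synthetic cohorts

The generator emits the seven MIMIC-schema CSV tables from a discrete
trajectory mixture in which every decision dimension has at least one
discriminating pattern: a new stage ≥ 2 (cases everywhere), stage-1-only
(separates D4 = 1 from 2), improving DTI (separates D7), admission
unstageable later staged and admission DTI that worsens (exercise the
encodings), note-only and ICD-only evidence (separate D6/D8 from staging),
and present-on-admission PIs (the common screen). Default conditions: 7%
of stays get a case-generating trajectory, 10% in-hospital mortality, ages
normal(65, 16) truncated to [16, 89], log-normal stay durations with a
five-day median, PI onset 25 h + exponential(48 h), per-source emission
probabilities (chart 1.0, note 0.8, ICD-9 0.4, procedure 0.05) mirroring
the field's reliability ordering of the sources, a 10% negated-mention
rate and 5% date-only notes. Notes are template sentences over a PI-free
filler vocabulary — enough for lexicon/negation logic and bag-of-words
separability, deliberately not realistic clinical language. An optional
signal token planted in the notes of case-trajectory stays makes the
benchmark separable by construction for sanity checks.

Ground truth records each stay's pattern, demographics and the per-source
evidence actually emitted. A second, deliberately naive labeler — a direct
loop-based transcription of the policy table kept in the test tree —
provides the independent oracle the engine is verified against on random
cohorts; passing says the engine implements the stated semantics exactly,
not that the lexicon or stage map matches any particular hospital's data.

## Known limitations

* One PI per stay: no anatomical matching of concurrent injuries.
* Negation is trigger-window only; complex textual negation will produce
  false-positive mentions on real notes.
* Default keyword, stage-item and code lists are emulations; counts on a
  real MIMIC export depend on the configured lists.
* The sequence classifier is a compact reference model, not a tuned
  production architecture.
* Synthetic notes cannot probe language understanding; benchmark results on
  generated cohorts validate the pipeline's plumbing and leakage
  guarantees, not clinical NLP performance.
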