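# Methods

This note documents the models and procedures implemented in `roipack`,
the parameter defaults and why they were chosen, and the limits of what
the synthetic phantom corpus can demonstrate.

## Segmentation: region-based active contour

The ROI/non-ROI split is the Chan–Vese two-phase piecewise-constant
level-set model. On intensities normalised to [0, 1], the mask Ω locally
minimises

    E(Ω) = μ·Length(∂Ω) + λ_in · Σ_{p∈Ω} (I_p − c_in)²
                        + λ_out · Σ_{p∉Ω} (I_p − c_out)²,

with c_in/c_out the phase means. The solver is explicit gradient descent
on a level-set function with a smoothed Dirac localiser, plus two
safeguards that make its behaviour easy to reason about:

* **Monotone energy.** Each candidate step is evaluated against the
  *discrete* energy of the thresholded mask (crack-boundary perimeter +
  exact sums of squares). A step that would raise E triggers step-size
  backtracking (halving, up to 8 times); if no step helps, the evolution
  stops. The energy trace is therefore non-increasing by construction,
  and the test suite asserts this per run.
* **Pointwise refinement.** After the level-set phase, pixels whose
  individual flip lowers E (fidelity delta plus μ times the local
  perimeter delta) are flipped in vectorised sweeps, again accepted only
  if the true energy does not increase. This sharpens the boundary below
  the smoothing scale of the level set; on clean phantoms the final mask
  matches the generating mask essentially exactly (Dice ≈ 1.0).

Defaults: `mu=0.2` (on the normalised intensity scale, i.e. 0.2·range²
in raw grey levels), `lambda_in=lambda_out=1`, `eps=1.0`, `dt=0.5`,
`max_iter=300`, `tol=1e-3` (fraction of pixels changing phase),
`init="otsu"`. The Otsu-seeded initial level set (smoothed image minus
its Otsu threshold) was chosen as default over the classical
checkerboard: with energy backtracking, the checkerboard start can stall
in a poor local minimum on low-contrast frames, while the Otsu seed
starts near the basin of the anatomical optimum and converges in a
handful of iterations. Checkerboard and disk initialisations remain
available.

The ROI is the *brighter* converged phase (MR anatomy on near-black
background); an exact tie of phase means, a constant image, or a
single-phase collapse raise explicit degenerate-input errors.
`min_component_px=64` returns converged foreground components smaller
than 64 px to the background: burned-in glyphs are at most 5×7 = 35 px
and are bright, but they are annotation, not anatomy; without the filter
the bright phase legally absorbs them and the text would never reach the
OCR stage. Setting 0 disables the filter.

Only the rectangular bounding box of the mask (padded by 2 px by
default) is stored, not the mask itself: every pixel inside the box is
compressed losslessly, a superset of the ROI, so no mask section is
needed in the container.

## Lossless ROI codec

The ROI crop is coded with the LOCO-I core of JPEG-LS:

* median-edge-detector prediction from neighbours a (left), b (above),
  c (above-left);
* context modelling on the quantized gradients (d−b, b−c, c−a), 9 levels
  each, sign-folded into 365 regular contexts, with per-context bias
  correction C[q] and adaptive Golomb parameter k (smallest k with
  N[q]·2ᵏ ≥ A[q]);
* Rice mapping M(e) = 2e for e ≥ 0, −2e−1 otherwise, and limited-length
  Golomb–Rice coding with an escape to a fixed-width code;
* run mode when all three gradients vanish: MELCODE-style run-length
  ramp (J table), two run-interruption contexts, standard reset
  discipline (counter halving at N = 64).

Run mode is included deliberately: without it the coder floors at about
one bit per sample on flat regions, whereas a constant 512×512 16-bit
plane should (and does) shrink to well under 1% of raw size. Encoder and
decoder execute the identical state machine; tests assert equality of
the full A/B/C/N/Nn state after coding.

The stream is **not** interchange-conformant JPEG-LS: there are no JPEG
markers, the k = 0 bias special-case mapping of the ISO bitstream is
omitted in favour of the plain Rice mapping, and each stream instead
carries a 13-byte header (magic `JLS1`, rows, cols as u32 LE, bits as
u8). Losslessness — the only property the pipeline relies on — is
guaranteed by construction and covered by randomised round-trip tests
over all bit depths 8–16. Near-lossless mode (NEAR > 0) and colour
transforms are out of scope.

## OCR and Huffman coding of the non-ROI

OCR is deterministic template matching against the shared 5×7 monospaced
bitmap atlas (A–Z, 0–9, punctuation). Ink pixels (above threshold,
outside the stored region) are labelled with 8-connectivity, grouped
into horizontal bands by vertical overlap, and each band's glyph-grid
origin is found by searching the ≤ 7×5 candidate offsets for the minimal
total Hamming distance; an exact render scores zero at the true origin.
Cells map to their nearest glyph (ties break on code point; blank cells
are spaces); a cell farther than 8 bits from every glyph flags the run
as `unmatched` instead of being dropped. The binarisation threshold is
`max(Otsu(non-ROI pixels), 0.25·range)`: the absolute floor encodes the
assumption that burned-in overlays are bright, and makes "text too dim
to recover" a well-defined outcome instead of letting Otsu adapt to any
bimodal histogram. Both the threshold and the floor are overridable. A
general OCR engine could be slotted in behind the same interface for
real scans, at the cost of the exact round-trip guarantee.

The serialized text records (frame dimensions, metadata whitelist pairs,
runs with anchors and intensity, as deterministic JSON) are coded with a
canonical Huffman code: optimal lengths from the byte frequencies
(deterministic tie-breaking: lowest total frequency, then lowest minimum
symbol), codes reassigned canonically so the codebook serialises as
(symbol, length) pairs only. A single-symbol alphabet takes the 1-bit
code `0` (the documented Kraft-sum exception).

## Container and archive

The `.mipp` package is the four-section layout documented byte-by-byte
in `roipack/container.py`: one shared Huffman codebook per package,
the coded text payload, the image count, and per image a size-prefixed
ROI stream with its bbox, frame dimensions and bit depth (the
reconstruction needs width/height and the paste position, so they ride
with each ROI record). A magic number and format version were added for
safe evolution. Every size prefix is validated on read; truncation
errors name the section.

The archive stores packages under their integer HIMS ID with GridFS-style
chunking (default 255 KiB chunks; an md5 checksum and length are verified
on reassembly). Hash indexes on citizenship id, name and surname and a
sorted (date, id) list are maintained on every put, so criteria search is
index-backed; results are ascending HIMS IDs, date ranges are half-open
[start, end) on ISO-8601 strings, and an unbounded no-criteria scan is
refused unless explicitly allowed. Backends (in-memory, file-directory)
are pluggable behind a small protocol and differentially tested.

## Parallelism

`compress_package` follows a scatter-gather contract: per-image map
tasks run in a thread pool of configurable width, the reduce step
consolidates in deterministic input order. Output bytes are invariant to
worker count and completion order (tested for workers ∈ {1, 2, 4}).
Cluster scheduling is an operational concern outside the library.

## Phantom corpus: what it shows and what it does not

`generate_phantom` emulates the structure the pipeline exploits: a
smooth bright anatomy region (2–5 Gaussian bumps thresholded at the
exact quantile realising the requested ROI area fraction — the
smoothness of the field supplies the smoothing the threshold needs), a
black background, monospaced burned-in text in the top margin disjoint
from the ROI, and additive Gaussian noise. Defaults: 256×256, 16 bits,
ROI fraction 0.3284, noise σ = 64 grey levels (≈ 0.1% of the 16-bit
range) confined to the ROI, text at full intensity; the acceptance
script scales the frame to 512×512. Anatomy intensities span 40–85% of
range so the foreground/background contrast is unambiguous.

Noise is confined to the ROI by default so the claim "the discarded
background carries no information" is exercisable in its pure form, and
full-frame reconstruction is then exactly lossless; `noise_global=True`
puts noise everywhere, in which case only the content guarantees (ROI
bbox pixels, annotation records) hold and background noise is genuinely
lost. Batch sizes in the tests (20 phantoms for compression and Dice
statistics, 50 for the end-to-end loop, 6 for parallel invariance) keep
the whole suite in the tens of seconds while the statistics are already
stable at those sizes.

Passing on phantoms does **not** show: robustness to anti-aliased or
proportional fonts, rotated text, unknown fonts (real annotation
overlays vary), anatomy touching the frame border, multi-coil intensity
inhomogeneity, or compressed-transfer-syntax DICOM inputs. Real MR
frames also compress less than smooth phantoms; the ROI fold ratio
measured here (≈ 2.4 at default noise) should be read as
codec-functioning evidence, not as a clinical compression estimate.

## Known limitations

* Anything outside the stored bbox that is neither black background nor
  recognisable text is irrecoverably lost — that is the method's design
  trade-off, inherited by construction. Unmatched ink is flagged on the
  run rather than silently dropped, so callers can fall back to
  whole-frame storage when the assumption fails.
* The two-phase model cannot separate multiple tissue classes; it only
  answers "anatomy vs background".
* Metadata survival is whitelist-based (five archival fields plus
  geometry); arbitrary private tags do not round-trip.
* The archive provides no replication, authentication or encryption;
  those belong to the deployment, not the library.
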