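# Methods

## Spectral model

Each conformer's absorption spectrum is a sum of Gaussians in the energy
domain, one per excited state, centered at the vertical excitation energy
and scaled by the oscillator strength. The half-width at half-maximum is
read literally as the HWHM of the Gaussian, so σ = HWHM/√(2 ln 2); the
default HWHM is 0.1 eV. Composition in the energy domain (rather than in
wavelength) is the standard convention for convolving vertical
excitations and is what reproduces printed band maxima from printed
energies. Intensities are arbitrary units proportional to oscillator
strength — no molar-absorptivity prefactor — because every analysis here
compares band positions and shapes, never absolute extinction.

Energy↔wavelength conversion uses hc = 1239.84193 eV·nm (CODATA-derived).
Printed tables round energies to two decimals, so a derived wavelength
can differ from a printed one by 1 nm; consistency checks therefore use a
±1 nm band.

The default wavelength grid is 300–800 nm at 0.5 nm (1001 points), which
covers the dye's visible band system with the 0.1 eV bands sampled ~15
points per HWHM. Peak location refines the grid argmax with a three-point
parabola; exact intensity ties break toward the longer wavelength
(red-most peak). An empty excitation set broadens to the all-zero
spectrum rather than raising, so all-dark conformers can participate in
ensemble averages; peak-finding on an identically zero spectrum raises,
since "the position of no band" has no meaning.

Ensemble spectra are pointwise arithmetic means on a shared grid.
Averaging accumulates in extended precision so that the mean of k
identical spectra is bit-identical to the input, which in turn makes
pipeline reports reproducible byte for byte.

Note a shape fact that matters when comparing to two-band descriptions:
with HWHM 0.1 eV, the planar structure's two states (2.69 and 2.92 eV,
intensity ratio ≈ 7:1) produce a *single* local maximum with a shoulder
near 424 nm — a weak band 2.7σ from a strong one cannot form a separate
peak. Tests assert the shoulder, not a second maximum.

## Dihedral analysis

Torsions follow the IUPAC sign convention (clockwise positive looking
from the second to the third atom), computed with the atan2 half-plane
formula; the convention only needs internal consistency because all
analyzed quantities are deviations. Collinear consecutive atoms make the
torsion undefined and raise. Deviations from a reference angle are folded
by the rotor's symmetry period — 180° for phenyl, carboxylate and
dimethylamine, all two-fold symmetric (the rotation scans stop at 90°
precisely because a half-turn is chemically equivalent) — giving values
in [0, period/2].

Kernel density estimates use a Gaussian kernel with Scott's-rule
bandwidth h = σ̂·n^(−1/5), with σ̂ the plain sample standard deviation
(matching the common plotting-software default, not the IQR-robust
variant), floored at 0.5° to guard near-degenerate samples. The
evaluation grid spans the sample range padded by 5 bandwidths at 0.25°
spacing; the mode is the grid argmax with parabolic refinement.
Zero-variance samples return a flagged point mass. Circular statistics
are deliberately avoided: after folding, samples live on [0, 90°], far
from any wrap-around; this is a documented limitation for hypothetical
samples near ±180°.

Rotamer populations are histogram fractions on user-supplied edges
(half-open bins, last bin closed); values outside the edges are an error
rather than silently dropped.

## Rotation surrogate

The conformation→excitation map interpolates a packaged,
checksum-verified table of constrained single-group rotation scans
(phenyl to 30°, carboxylate and dimethylamine to 90°; two states per
node; shared planar reference at Δd = 0 with E₁ = 2.69 eV, f₁ = 0.8695).
Energy and oscillator strength are interpolated separately per state with
monotone shape-preserving piecewise cubics (PCHIP): node values are
reproduced exactly (node hits bypass the interpolant entirely, so the
90°-amine dark state is *exactly* f₁ = 0), and no overshoot means
strengths never go negative between nodes. Angles beyond a group's last
node — possible only before folding — clamp to the last node.

States are interpolated energy-ordered, not character-tracked: the
carboxylate scan exchanges state characters near 30° (the printed
contributions mix), and tracking characters through an avoided crossing
from two-state data would be guesswork.

For snapshots with several groups rotated at once, the surrogate assumes
first-order independence relative to the planar reference: energy shifts
add, oscillator-strength ratios multiply (floored at 0), and states are
re-sorted by energy afterwards. The underlying scans rotate one group at
a time, so this combination rule is a heuristic, validated only at the
printed nodes and by qualitative ensemble behavior (red shift with amine
rotation, dark-state limit); it is not claimed to reproduce per-snapshot
TD-DFT quantitatively. The surrogate emits two-state excitation sets
because the calibration table provides two states — consistent with the
finding that the lowest-energy spectral range needs only the lowest few
states, of which two carry weight.

## Synthetic ensembles

The generators emulate the *marginal* dihedral distributions the
reference dynamics exhibit, as truncated normals (deg):

| group | mode | σ | truncation | emulates |
|---|---|---|---|---|
| Ph | 5 | 7 | [0, 20] | phenyl nearly perpendicular, deviations ≤ 20° |
| COO | 12.5 | 5 | [0, 45] | carboxylate twist concentrated at 10–15° |
| NMe2 | 40 | 22 | [0, 100] | floppy amine, density peak ≈ 40°, support to 100° |
| BOMD amine | 20 | 18 | [0, 90] | deviation from planarity, mode ≈ 20°, support to 90° |

Modes and truncations are the stated ranges of the reference
distributions; the σ values are this package's own choices, picked so the
truncated densities reproduce the verbal mode/extent descriptions (they
were described only as violin plots, never as numbers). All parameters
are exposed as configuration; mixtures of truncated normals are supported
for bimodal scenarios. MD-like amine draws are generated on [0, 100°] and
folded to [0, 90°] only at surrogate time, so the generator's own
distribution (and its KDE mode) is analyzed unfolded. The BOMD generator
is kept separate because its angle is an absolute deviation from
planarity, not a deviation from the DFT-optimized geometry.

Snapshots are drawn independently: no autocorrelation in time and no
coupling between groups. Passing tests therefore demonstrate that the
pipeline machinery (folding, surrogate, broadening, averaging,
statistics) behaves correctly under realistic marginals — not that real
trajectories are reproduced, and not that ensemble lineshapes match any
particular measured spectrum.

The experimental-style reference spectrum is a synthetic two-Gaussian
model in wavelength: main band at 550 nm (σ 18 nm), secondary at 510 nm
(σ 33 nm, broad enough that the envelope decays into the ~400 nm region),
secondary/main peak ratio 0.6 (a qualitative "less intense" reading —
only the 550/510 centers are literature values). Because the bands
overlap, pinning the main Gaussian at 550 nm would put the *composite*
maximum ~3 nm to the blue; the constructor calibrates the main-band
center by fixed-point iteration on a 0.01 nm grid so the composite
maximum sits at 550 nm exactly.

## Pipeline and comparison

A run is one `RunConfig` (YAML-loadable) with exactly one input mode —
synthetic ensemble, XYZ trajectory plus dihedral specs (0-based atom
indices), or a neutral excitation table — and is deterministic end to
end: subset averaging samples k snapshots without replacement from a
seeded generator (the reference analysis says only "randomly selected";
this protocol is ours), and reports are JSON with sorted keys and no
timestamps, so identical configs give byte-identical reports.

`compare_to_reference` resamples the reference onto the simulated grid,
peak-normalizes both for the peak displacement, and reports band overlap
as the integral of the pointwise minimum of the *area*-normalized curves
(1 = identical shape, 0 = disjoint). How measured and simulated spectra
are mutually normalized is a convention with no canonical answer; the
choice is recorded in the comparison record itself.

The headline "nearly 80 nm" ensemble red shift of the literature is a
qualitative anchor whose exact reference pair is unstated; the package
exposes `band_shift` and reports whatever the configured ensemble gives
(+14 nm for the default 20-snapshot MD-like ensemble at seed 0, because
the oscillator-strength decay at large amine angles damps the far-red
contribution under the independence heuristic) rather than asserting 80.

## Problem sizes and numerical checks

Default analyses use 20–100 snapshots per ensemble (matching the
reference protocol, where 20 snapshots already converge the peak and 100
add nothing), 5000 draws for distribution-mode estimation, and the
1001-point default grid; all complete in seconds. KDE mode recovery is
validated at n = 5000 over 100 seeded replicates (≥ 95% within ±5°);
at n = 100 per condition the λmax-vs-amine-mode sweep is monotone for
typical seeds, with sampling noise on the order of the 1–3 nm
adjacent-condition spacing (the systematic trend was verified at
n = 4000). Broadening is cross-checked against a brute-force per-point
double loop (10⁻¹² relative) and against the closed-form Gaussian area
(σ√(2π)·Σf, 0.5%); torsions are cross-checked against MDAnalysis at its
float32 precision.
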