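# Methods

## Model

A protein is coarse-grained to one node per residue at the C-alpha position.
Residue pairs whose C-alpha distance satisfies `R_ij <= r_c` (boundary
inclusive; default `r_c = 7.0 Å`) are joined by identical harmonic springs
of force constant `γ`, giving the Gaussian network model potential

    V = (γ/2) ΔRᵀ Γ ΔR

with Γ the Kirchhoff matrix (graph Laplacian) of the contact network:
Γ_ij = −1 for a contact, 0 otherwise, and Γ_ii the contact degree.  All
residues carry the same mass `m`.  In the default natural units γ = m = 1,
time is measured in units of √(m/γ); both constants are configurable and
every normalized quantity is independent of them.

Eigendecomposition Γ = U Λ Uᵀ yields the normal modes.  A connected network
has exactly one zero eigenvalue, whose uniform eigenvector is the overall
translation; it is removed from every dynamical and thermodynamical sum.
More than one numerical zero mode means the contact graph is disconnected,
which is refused (mode-space dynamics would silently ignore transport
between components) rather than analysed.

Equilibrium observables are mode sums equal to pseudo-inverse elements:
MSF_i = (3 k_B T/γ)[Γ⁺]_ii and the normalized cross-correlation
C_ij = [Γ⁺]_ij / √([Γ⁺]_ii [Γ⁺]_jj) ∈ [−1, 1].

## Non-equilibrium response

The perturbation is an initial displacement of amplitude 1 (configurable)
on a single residue m, optionally with an initial velocity.  Because the
equation of motion d²ΔR/dt² = −(γ/m) Γ ΔR is linear, the response is exact
in mode space:

    ΔR(t) = Σ_k U_k [A_k cos(ω_k t) + B_k sin(ω_k t)],
    A_k = U_mk·d,  B_k = U_mk·v/ω_k,  ω_k = √((γ/m) Λ_kk)

summed over non-zero modes.  With zero initial velocity all phases vanish
and the solution is the pure cosine sum; at t = 0 it equals the perturbation
vector minus its uniform component, ΔR_i(0) = δ_im − 1/N.  The evaluation is
closed-form — the time grid only samples it, it introduces no integration
error.

A residue is *excited* when its response metric first reaches a threshold;
the metric is either the amplitude |ΔR_i(t)| or the squared fluctuation
ΔR_i(t)².  The excitation time is the first grid time at or above the
threshold, with no sub-grid interpolation: the grid step is the reported
resolution.  Default grid t ∈ [0, 20] at dt = 0.001 (units √(m/γ)) — the
published excitation times carry three decimals, the earliest being 0.001
and the latest 13.420, so this grid resolves them with margin.  The
perturbed residue trivially crosses at t = 0 and is flagged as the source.
Published case studies state the threshold inconsistently (squared
fluctuation > 0.01 in one place, amplitude > 0.015/0.01 in others), so the
CLI reproduction commands require metric and threshold explicitly and the
`reproduce` subcommand runs both conventions and prints the counts under
each.

## Pathways

Excited residues are grouped into clusters either by sequence contiguity
(maximal runs with gaps up to `gap_tolerance` residues, default 2 — the
published clusters contain single-residue interior gaps) or, when an
annotation file is supplied, by identical secondary-structure label
(residues on the same strand/loop/helix form one cluster regardless of
sequence gaps).  A cluster's excitation time is its earliest member time;
its central residue is the member with the largest peak metric (ties to the
lowest serial — the published analyses name central residues but state no
rule).  Clusters sorted by excitation time give the pathway; ties break by
Euclidean distance of the central residue to the source, then serial.
Branch splits (e.g. a pathway toward two different subdomains) are a
structural judgement, so they are user-supplied cluster partitions ordered
independently, not computed.

Anisotropy is quantified by relating each residue's peak metric to its hop
count from the source (Dijkstra with unit edge weights — identical to BFS
depth, which the tests use as the independent oracle) and to its Euclidean
distance, summarized by Spearman rank correlations (the comparison in the
literature is a qualitative scatter; Spearman is this package's choice of
summary statistic).  The equilibrium comparison selects the
⌈fraction·(N−1)⌉ residues most correlated with the source, ranked by signed
correlation by default (absolute ranking available; the convention is not
stated in the literature).

## Numerical choices

- Zero-mode tolerance: |λ| < 1e−10 · λ_max (eigensolvers return ~1e−14-scale
  values for the analytic zero).
- Eigenvector signs fixed so each column's largest-magnitude entry is
  positive; observables are sign-invariant, this only stabilizes serialized
  output.  Degenerate eigenspaces (symmetric synthetic structures) may mix
  basis vectors; all exported quantities are basis-invariant, which the ring
  symmetry tests exercise.
- Altloc handling in PDB input: highest occupancy wins, ties by altloc
  identifier; residues lacking a C-alpha are skipped with a warning;
  calcium ions (atom name CA, element Ca) are never nodes.
- The velocity-Verlet oracle integrates the unprojected initial condition
  and subtracts the per-frame mean (the zero-mode component) afterwards —
  mathematically equivalent to mode removal and therefore an independent
  check of it.  It warns when dt·ω_max ≥ 0.1 and refuses runs whose total
  energy drifts by more than 1%.

## Synthetic structures and what they show

`make_synthetic` produces point chains, rings and cubic lattices with exact
spacing — analytically tractable geometries, not proteins.  They exercise
the dynamics (closed forms on the 2- and 3-node chains), symmetry
(rotation-invariance on rings) and the isotropic control: on a ring the
peak response decays monotonically with hop distance *provided the
observation window ends before the two wavefronts meet at the antipode*
(group velocity ≤ 1 hop per time unit, so a 48-node ring is free of
wrap-around within t ≤ 20; smaller rings show recurrences that break
monotonicity, which is real physics, not an artifact).  Random connected
test networks are sub-cutoff random walks in 3-D: connected by
construction, with incidental nonlocal contacts.  None of these reproduce
real contact-network heterogeneity, so passing synthetic tests validates
the mathematics, not biological conclusions; the case-study regressions on
the real myosin (PDB 1MMA) and PDZ3 (PDB 1BE9) structures require those
files locally (`gnmflow reproduce <case> --pdb-dir data --fetch`) and the
published excitation counts and cluster times are sensitive to chain
selection (e.g. whether the PDZ3-bound peptide chain contributes nodes,
exposed as `--include-peptide`) and to the threshold convention; the
regression reports the configuration under which each count is matched.

## Limitations

- Scalar (isotropic) GNM only: no 3N×3N anisotropic Hessian, no
  distance-weighted springs.
- No damping, thermal coupling or ensembles — the dynamics is conservative
  and deterministic by design.
- Secondary-structure assignment is not computed; annotation files are
  external input.
- Problem sizes: the analytic route is a dense eigendecomposition plus a
  (T×K)·(K×N) product; a ~750-residue protein on the default 20001-point
  grid needs a few seconds and ~120 MB.
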