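# Methods

`swaloop` rebuilds a protein loop of length N inside a fixed scaffold by
stepwise assembly: enumerative, residue-by-residue growth of the loop from
both ends over a dynamic-programming-style stage graph, with side-chain
optimization at every step, CCD chain closure when the two fragments come
within 1–3 residues of each other, energy-ranked leader clustering, and
continuous torsion-space minimization. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Conformational model

Bond lengths and angles are fixed at the ideal values shipped in
`data/ideal_geometry.yaml` (Engh–Huber-like backbone values; side-chain
templates with heavy atoms plus polar hydrogens only). The only degrees of
freedom anywhere are torsions: phi/psi/omega per residue and chi per
side-chain. Fragment coordinates are derived from torsions by sequential
NeRF-style placement from the two scaffold anchor residues; the scaffold
backbone never moves. The residue numbering is 1-based and matches the
FASTA position; torsions are degrees in all interfaces.

A growing N-terminal fragment ends in a methylamide cap and a growing
C-terminal fragment starts with an acetyl cap; the caps present the next
peptide unit's amide/carbonyl groups for hydrogen bonding and disappear
automatically once the adjacent residue is built. A formally closed chain
carries a cutpoint with three virtual atoms (N, CA on the N side; C on the
C side) that coincide with their real counterparts iff closure is exact;
the cutpoint may sit anywhere inside the loop or at either loop boundary.

Proline: phi is pinned at −65° (the ring constrains it), the ring is a
rigid ideal template, and the peptide bond before a proline is also sampled
cis (omega = 0°). Backbone amide hydrogens are placed anti to the preceding
carbonyl carbon; the hydrogen on the residue after the loop is only rebuilt
when `sample_loop_takeoff` is enabled, which is off by default (the takeoff
psi of residue k−1 and the phi of residue l+1 are then fixed at the values
implied by the scaffold's O and H atoms).

## Surrogate energy function

The energy is a transparent surrogate with the term structure the protocol
needs; one energy unit is treated as one k_BT everywhere (retention
windows, the 1-unit convergence gap).

* **Packing** (`fa_atr`/`fa_rep`): a split Lennard-Jones on heavy-atom
  pairs, r_min = sum of per-element radii (C 1.75, N 1.55, O 1.50, S 1.80 Å),
  well depth 0.20 units, cosine-switched to zero at the 6 Å pair cutoff.
  Below r_min the attractive branch stays at −eps and the repulsive branch
  rises, continued linearly below 0.6·r_min so grid-sampled clashes score
  poorly but finitely. Pairs within four bonds are excluded: local,
  torsion-determined preferences belong to the rama and rotamer terms, and
  a *closed* cutpoint still counts as bonded for exclusions (the chainbreak
  term, not sterics, polices the residual deviation).
* **Hydrogen bonds** (`hbond_bb`/`hbond_sc`): E = −switch(d)·gauss(d)·
  max(0, cos θ)², with d the donor–acceptor heavy-atom distance (well at
  2.9 Å, hard zero at 3.2 Å) and θ the deviation of H···A from the D–H
  direction. Backbone–backbone pairs are weighted by `hbond_bb`, anything
  involving a side-chain by `hbond_sc`. There is deliberately no burial or
  solvent-exposure attenuation in either dialect.
* **Backbone torsions** (`rama`): 20°-binned (phi, psi) tables for four
  residue classes (generic, glycine, proline, pre-proline), built at load
  time from periodic Gaussian basins encoding the textbook allowed regions
  (`data/rama_basins.yaml`), normalized so the minimum is −1 and
  interpolated bilinearly. The construction is fully self-contained — no
  external data enters at build time. The sampling filter discards grid
  points scoring above 0.8 units; the basin widths are such that roughly
  20–40 of the 324 grid points survive per residue, so the filter is doing
  real work while every canonical basin remains buildable.
* **Side-chain torsions** (`rotamer`): ½(1 + cos 3χ) per sp3 chi —
  staggered conformers preferred, eclipsed penalized; terminal sp2 chis are
  flat.
* **Chainbreak** (`linear_chainbreak`): the sum of the three virtual/real
  atom-pair deviations in Å, applied with weight 150 during and after
  closure. The *closure deviation* reported everywhere is the RMS over the
  three pairs, √(Σd²/3); this is also the quantity screened at 1.5 Å.
* **Coordinate restraint** (`coordinate_constraint`): per-residue fade
  spline on the CA deviation from a reference — zero up to 2 Å, 10 units
  beyond 4 Å, the unique zero-slope Hermite cubic in between.

Two weight dialects exist: *sampling* (fa_rep 0.10, hbond_sc 3.1) forgives
the discreteness of grids and rotamers during enumeration and packing;
*minimization* (fa_rep 0.44, hbond_sc 1.1) is used for continuous
minimization and all model ranking.

Known limitation: there is no solvation term of any kind, so
solvent-exposed conformations are systematically over-compact relative to
real proteins; the surrogate is a vehicle for exercising the search
algorithm, not a predictor for experimental structures.

## Search protocol

Each stage (i, j) holds an ensemble of at most 400 models with the
N-fragment built through residue i and the C-fragment back through j. A
growth step appends (or prepends) a capped residue to every parent model,
enumerates (phi, psi) on a 20° grid (18 samples per torsion, left-inclusive
from −180°) for the new residue and — when `sample_adjacent` is on — the
fragment-adjacent residue, discards rama-filtered points, runs seeded
rotamer trials (canonical rotamers plus ±1 σ expansions of chi1/chi2) on
the sampled residues and their Cβ-distance neighbor list (10 Å), clusters
at 0.10 Å over the rebuilt backbone atoms without superposition (the
scaffold frame is shared), keeps the lowest 400, minimizes each survivor
(L-BFGS over the new residue's phi/psi/omega and neighboring chis), and
clusters again. Stage collation keeps the 4000 lowest incoming models,
reclusters at 0.25 Å over the whole rebuilt fragment, and carries 400
forward.

Closure: stages with 1–3 gap residues are closed by grid-sampling the first
(or, in the mirror variant, the last) gap residue and running up to 1000
CCD cycles on the remaining bridge torsions — each update sets one torsion
to the analytic angle minimizing the summed squared deviation of the three
closure atom pairs, so the deviation never increases. Candidates at or
beyond 1.5 Å RMS deviation are discarded. Pure-N and pure-C fragment
ensembles are additionally recombined pairwise (ranked by summed fragment
energy, capped by `recombine_max_pairs`) and closed through the same
machinery. All screened candidates from every closure route are pooled,
clustered, re-packed, re-closed by a full-loop CCD pass where needed, and
minimized over all loop torsions and neighboring side-chains with the
chainbreak weight at 150 — this is what drives final closure deviations
below 0.01 Å. The final pool is reclustered at 1.0 Å over loop CAs and the
five lowest-energy models, after a longer polish minimization, are the
predictions.

The linear (O(N)) calculation grows each fragment alone and closes at the
end; the full (O(N²)) recursion visits all (i, j). The standard policy
(`mode: auto`) runs linear first and escalates to full when the energy gap
between the two lowest final models is under 1 unit.

Determinism: all stochasticity (rotamer-trial visit order, annealing) flows
from one master seed through stable per-edge hashes, so rerunning a
configuration reproduces the result bit-for-bit, and stages without shared
ancestry could be executed in any order without changing it.

## Minimization

Quasi-Newton descent (scipy L-BFGS-B) over the move-set torsion vector,
unwrapped in degrees and re-wrapped on write-back. Gradients are forward
finite differences (h = 0.05°) inside the optimizer, with a best-seen
tracker guaranteeing the returned point never scores above the start;
the package's gradient *oracle* (`numerical_gradient`) is central
differences, and its correctness is checked by step-halving consistency.
Only interactions touching residues that can move are recomputed per
evaluation; the static remainder is cached once (the cached-plus-movable
total matches a full recompute to 1e-6).

## Synthetic fixtures and what they do (and do not) show

`make_scaffold` builds 15–60-residue beta-hairpin or helix-turn-helix
chains from canonical torsions with seeded ±4° jitter and a sequence drawn
from {A, S, V, L, T, G}, packs the side-chains, relaxes all torsions, and
rejects clashed results. `make_recovery_problem` excises a loop, polishes
it in place (chainbreak weight 150) until it is a strong local optimum of
the minimization-dialect energy, records that as the planted native, and
strips the loop plus every side-chain from the problem file — the same
input convention as a crystallographic loop-rebuilding benchmark.

Because the planted native is an optimum of the very energy being searched,
recovery is a pure sampling test: failures diagnose the search, not the
energy model. Conversely, success on these fixtures says nothing about
accuracy on real proteins, where the energy model (and in particular the
missing solvation term) dominates. Real crystallographic loops also carry
non-ideal geometry, alternate conformers and crystal contacts that the
generator does not emulate.

## Desk-scale study conditions

The full-scale protocol (400-model stages, adjacent-residue sampling,
full recursion) costs thousands of CPU hours per loop. The shipped
`RunConfig.coarse()` preset keeps the protocol and all thresholds — 20°
grid, 0.8 rama filter, 0.10/0.25/1.0 Å cluster radii, 1.5 Å closure
screen, chainbreak weight 150, 1-unit convergence gap — but carries 8
models per stage (collating 60), samples only the new residue's backbone,
runs one rotamer sweep and short per-stage minimizations (12/18 L-BFGS
iterations, 100 for the final polish), and caps recombination at 12 pairs.
Under these conditions a complete linear-mode rebuild of a 4–6-residue
loop on a 16–20-residue scaffold takes two to five minutes on one CPU.
The bundled studies use loop lengths 4–6 and scaffolds of 16–20 residues;
planted-optimum recovery at these sizes is reliable on helix-turn
scaffolds, while beta-hairpin loops — whose intermediates are barely
stabilized until the cross-strand hydrogen bonds form — often recover the
closed, low-energy state but not the exact native register, the expected
failure mode for build-up methods at this ensemble size.

## Numerical choices and degenerate inputs

* Ties in clustering and retention break by (energy, insertion order);
  insertion order is itself deterministic (parent, then grid index).
* CCD stops at deviation < 1e-4 Å, on stall (< 1e-9 improvement per
  cycle), or at the cycle cap; a gap of one residue makes the two closure
  variants identical and only one is run.
* The closure screen, all cluster RMSDs and the final-selection RMSD are
  computed without superposition: the scaffold is rigidly fixed, so all
  models share a frame.
* An empty stage ensemble propagates as empty (downstream stages skip); an
  impossible filter yields zero predictions rather than an error.
* Duplicate atoms at zero distance score at the finite repulsion cap;
  non-finite coordinates raise immediately.
* PDB output rounds to 1e-3 Å (format precision); cap and virtual atoms
  are never written.

## Limitations

* The surrogate energy is not a production molecular-mechanics score and
  its absolute values are not comparable to any published force-field
  energies; only the algorithmic behavior (closure quality, convergence,
  planted-optimum recovery, retention arithmetic) is meaningful.
* The rotamer library is backbone-independent and coarse (three states per
  sp3 chi); real rotamer statistics are backbone-dependent.
* Kinematic (analytic) closure is not implemented; CCD plus
  chainbreak-weighted minimization is the only closure route.
* The in-process scheduler replaces any cluster/job-farm machinery; stage
  outputs are plain directories and runs are single-process.
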