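# Methods

## Model

Conduction velocity in the infarct border zone is reduced by convex
wavefront curvature arising from thin-to-thick changes in border-zone
thickness T:

    theta = theta_o - (D / c) * (dT / T)        (space-step form)
    theta = theta_o - D * rho,  rho = (dT/T)/c  (curvature form)

theta_o is the rectilinear velocity (default 0.4 mm/ms, ventricular
myocardium), D the diffusion coefficient (0.1 mm²/ms), c the space step
(1 mm) and dT the largest thickness increase over c in any of 8 compass
directions about the node (bilinear interpolation for off-lattice
samples).  dT is one-sided: only thin-to-thick change slows a wavefront;
thick-to-thin change produces a concave, facilitated front and is handled
in the propagation solver.  theta reaches 0 at dT/T = theta_o·c/D = 4.0
with the defaults.

Rate dependence enters through the circular-arc model rho = 2·sin(beta)/w.
Three calibrated (cycle length, critical width) points — (200 ms, 0.60 mm),
(150 ms, 1.29 mm), (117 ms, 2.64 mm), beta = 90° — define the critical
curvature rho_crit(CL).  Between points, w is interpolated log-linearly in
CL (the three points are nearly exponential; no functional form is
prescribed by the source calibration).  `critical_width` refuses cycle
lengths outside [117, 200] ms unless extrapolation is requested; the
propagation solver *does* extrapolate, because drive-train cycles at
250–300 ms need a defined (very small) critical width — clamping at the
200 ms point would wrongly predict block of slow wavefronts over steep
lateral ramps.  For a transition of total relative change dT/T completed
over distance L, block at cycle length CL is predicted when the local
curvature (dT/T)/L ≥ rho_crit(CL), equivalently L ≤ the critical space
step c_crit = (dT/T)/rho_crit(CL) (1.6 / 3.4 / 6.9 mm at 200 / 150 /
117 ms for dT/T = 5.23).

## Synthetic thickness maps

`make_isthmus_map` emulates the canonical substrate: a thin channel
(231 μm) inside a thick outer pathway (1440 μm), with a steep entrance
transition (default 2 mm), a gradual exit transition (6 mm), and steep
lateral transitions (1.5 mm).  Ramps are linear in thickness over the
transition length (making dT/c constant and analytically checkable); where
end and lateral ramps overlap, the larger (steeper) governs, keeping the
field monotone outward from the channel.  Channel width 10 mm and length
23 mm are package choices matching the observed mean isthmus length.
Maps are node-centered square grids; thickness is stored in μm, distances
in mm; rasters are delimited text with a `# spacing_mm=` header.

What the generator does *not* emulate: real maps are irregular, anisotropic
and contain holes (non-viable tissue); transitions are not linear; the
outer pathway is not uniformly thick.  Passing tests therefore demonstrate
the model's internal consistency and its qualitative paradigm on idealized
substrates, not predictive accuracy on measured anatomy.  Masks read from
rasters (nan cells) are honored by the solver.

## Propagation solver

Activation marching is single-source Dijkstra on the 8-connected grid.
Edge traversal time is edge length divided by a directional velocity from
the signed curvature law evaluated over the space step c along the edge
direction; thick-to-thin (negative) change accelerates the front, capped
at 1.5·theta_o (facilitation is real but its magnitude is not calibrated —
the cap prevents unphysical speed-up).  An edge is excluded (and recorded
as blocked) when the thin-to-thick transition ahead of it blocks at the
cycle being simulated: the profile ahead is scanned by bilinear sampling
in half-spacing steps up to 12 mm, stopping where it descends below 95% of
the local thickness; the transition length is the distance from the node
to 90% of the total rise.  Refractoriness is a uniform floor: a node
cannot activate before its prior-cycle activation plus ERP.  Unreached
nodes are nan.  The marching solution is checked against an
order-independent fixpoint relaxation oracle on random small maps; the
floor keeps relaxations monotone, so Dijkstra remains exact.

Because the block criterion is directional, block is unidirectional by
construction: the premature (S2) wavefront travelling thin-to-thick at the
steep entrance fails while the reverse traversal remains open.

## Premature protocol and reentry

`run_premature_protocol` marches the last S1 drive cycle, then the S2
cycle at the coupling interval (the S1 activation, shifted by the coupling
interval, supplies the refractory background).  Blocked S2 interfaces are
chained into polylines (interface midpoints linked within 1.2 grid steps);
the premature-cycle line is the UBL, its leading edge the vertex nearest
the stimulus.

Breakthrough: a blocked interface (u -> v) supports re-entry in the
reverse direction when the distal side v is still a depolarized source
when u recovers, i.e. t_u + ERP ≤ t_v + APD, and the reverse edge
conducts at the reentry cycle length.  The crossing fires at
max(t_v + edge time, t_u + ERP).  Defaults ERP = 100 ms and APD = 90 ms
encode modest post-repolarization refractoriness (ERP outlasts APD in 3–5
day border zone).  The 10 ms ERP−APD margin is what separates genuine
block lines — where the far side is reached the long way around, tens of
ms late — from collision interfaces, where both sides activate within a
couple of ms and repolarize together.  If no interface qualifies, the run
reports "no reentry induced".  The first reentry cycle (V1) is then
marched from the qualifying crossings at a cycle length defaulting to the
observed return time (~190 ms on the default substrate), with the S2
activation as refractory background; its blocked interfaces are the
lateral isthmus boundaries.  The reexcitation interval is the V1 minus S2
activation time at the breakthrough node.

## Circuit measurements

Lengths follow the standard overlay protocol: a = stimulus to UBL leading
edge; b = extent of the UBL along the isthmus long axis (the total
polyline arc length is also reported, `b_arc`, since the written
definition admits both readings); c = mean arc length of the two lateral
block lines; d = overlap of the UBL's and the lateral lines' extents
projected on the axis; e = mean of the minimum polyline-to-polyline
distances (shapely segment distances) from the UBL to each lateral line;
d/c as a percent.  The isthmus axis is the principal (SVD) direction of
the lateral polylines' vertices; all measurements are rigid-motion
invariant.  Summaries use the arithmetic mean and sample SD (ddof = 1).
The per-experiment canine tables shipped under `src/borderzone/data/` are
12-row transcriptions of published measurements; only per-experiment rows
are shipped and summary rows are recomputed.

## Numerical choices and defaults

| parameter | default | units | why |
|---|---|---|---|
| theta_o | 0.4 | mm/ms | rectilinear velocity in ventricular myocardium |
| D | 0.1 | mm²/ms | diffusion coefficient |
| c | 1.0 | mm | space step of the velocity law |
| beta | 90 | deg | isthmus opening to an expanse |
| ERP | 100 | ms | uniform; consistent with observed ~103 ms recovery sufficing |
| APD | 90 | ms | plateau-source duration; ERP − APD = post-repolarization refractoriness |
| facilitation cap | 1.5·theta_o | — | uncalibrated concave speed-up |
| profile scan | 12 mm, half-spacing steps | — | covers the largest relevant critical steps |
| grid spacing | 1.0 (generator), 0.5 (pipeline default) | mm | the 0.5 mm pipeline grid resolves the 1.5 mm lateral ramps, which a 1 mm grid represents as an effectively 2 mm transition (then too gradual for reentry-rate lateral block) |

The default simulation sizes (81 x 121 nodes at 0.5 mm; three marched
cycles) run in about a second; oracle comparisons use ≤ 7 x 7 maps where
exhaustive relaxation is cheap.

## Limitations

Isotropic conduction and uniform refractoriness only; no ionic kinetics,
no electrogram synthesis, no in-plane (XY) constriction curvature, no
anisotropy or safety-factor effects; a single verification reentry cycle
rather than sustained VT; measured (non-synthetic) thickness maps are
supported as input rasters but no imaging front-end is provided.  The
breakthrough timing on idealized open maps is dominated by the geometric
path difference around the block line, which is shorter than in mapped
hearts where pivot-point slowing and heterogeneous conduction add delay;
the reexcitation interval consequently sits at the ERP floor on the
default substrate.
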