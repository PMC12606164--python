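"""Screen fitted strain energies for physical admissibility.

Two conditions: C1 -- the energy surface W(lam1, lam2) must be free of
saddle points over the explored stretch range; C2 -- the collagen-fiber
energy must dominate the ground-matrix energy along the uniaxial path.
The soft ligamentum flavum (LF) fitted with a stiff Yeoh matrix is the
classic violator of C2.
"""

from ligfit.pipeline import admissibility, fit_ligament

for name, kind, mu, lam_max in [("ALL", "NH", 1.0, 1.35),
                                ("LF", "NH", 1.0, 1.25),
                                ("LF", "Yeoh", 2.0, 1.25)]:
    fr = fit_ligament(name, kind, mu, seed=0)
    c1, c2 = admissibility(fr.params, lam_max)
    msg = f"{name:4s} {kind + '+P4':8s} mu={mu:<4g} C1={'ok' if c1.satisfied else 'SADDLE'}"
    if c2.satisfied:
        msg += "  C2=ok (fibers dominate)"
    else:
        lo, hi = c2.failing_interval
        msg += f"  C2=VIOLATED on stretch [{lo:.3f}, {hi:.3f}]"
    print(msg)
# ALL at mu=1 passes both conditions.  LF with an NH matrix violates C2
# only in a narrow initial stretch range; with a stiff Yeoh matrix the
# ground substance carries more energy than the fibers essentially
# everywhere, which is non-physical for a collagenous ligament.
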