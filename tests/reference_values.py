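"""Worked-example per-line summary statistics for a ten-line second-order MA
fitness assay (one low-fitness line re-assayed with more controls).

These printed summary values are inputs to the group-summary and
Bateman-Mukai arithmetic tests: delta_M in 1e-3 per generation, V_M (both
scalings) in 1e-4, heritability in 1e-3; w and V_E* on the natural scale.
``None`` marks quantities undefined for a line whose mean fitness rose.
"""

# line, fitness, assay, w_ma, delta_m(e-3), v_m_star(e-4), v_e*_0, v_e*_ma,
# h2_m(e-3), v_m_control(e-4), u_min, e_a_max
WORKED_EXAMPLE_LINES = [
    ("504", "low", "a1", 0.57, -2.84, 5.25, 0.64, 0.94, 0.73, 1.84, 0.09, -0.04),
    ("508", "low", "a1", 0.58, -2.80, 0.22, 0.59, 1.18, 0.28, 0.07, 2.35, -0.00),
    ("547", "low", "a1", 0.67, -2.22, 3.61, 0.80, 1.06, 0.40, 1.10, 0.09, -0.02),
    ("550", "low", "a1", 0.88, -0.83, 0.82, 0.66, 0.79, 0.13, 0.63, 0.02, -0.04),
    ("579", "low", "a1", 1.47, 3.10, 0.15, 1.67, 1.26, 0.01, 0.31, None, None),
    ("579", "low", "a2", 0.97, -0.18, 6.52, 1.45, 1.73, 0.42, 6.44, 0.00, -1.84),
    ("522", "high", "a1", 0.79, -1.43, 3.57, 0.24, 0.21, 1.61, 1.81, 0.02, -0.06),
    ("537", "high", "a1", 0.81, -1.33, 2.21, 0.19, 0.27, 0.98, 1.38, 0.03, -0.05),
    ("566", "high", "a1", 0.93, -0.46, 2.33, 0.28, 0.35, 0.73, 1.81, 0.00, -0.20),
    ("583", "high", "a1", 0.99, -0.08, 3.29, 0.15, 0.26, 1.59, 3.12, 0.00, -1.91),
    ("587", "high", "a1", 0.85, -1.00, 4.76, 0.28, 0.39, 1.41, 3.13, 0.02, -0.16),
]

T_GENERATIONS = 150

# printed group summaries these inputs must reproduce (same units as above)
EXPECTED_DELTA_M_MEAN = {"high": -0.86, "low": -1.44, "all": -1.15}
EXPECTED_V_M_STAR_MEAN_ALL = 2.94
EXPECTED_U_MIN_MEAN_ALL = 0.26
EXPECTED_U_MIN_MEDIAN_ALL = 0.02


def worked_example_estimates():
    """The worked-example rows as LineEstimate objects (natural units)."""
    import numpy as np

    from mutacc.mutational_inference import LineEstimate

    out = []
    for (line, fitness, assay, w_ma, dm, vmstar, ve0, vema, h2, vmc, umin, ea) in WORKED_EXAMPLE_LINES:
        out.append(
            LineEstimate(
                line_id=line,
                assay_id=assay,
                fitness_class=fitness,
                t=T_GENERATIONS,
                delta_m=dm * 1e-3,
                v_m_control_scale=vmc * 1e-4,
                v_m_star=vmstar * 1e-4,
                h2_m=h2 * 1e-3,
                v_e_star_control=ve0,
                v_e_star_ma=vema,
                w0_mean=1.0,
                wma_mean=w_ma,
                u_min=umin,
                e_a_max=ea,
                flags={} if umin is not None else {"u_min_undefined": "mean fitness rose"},
            )
        )
    return out
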