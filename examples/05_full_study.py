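"""The whole pipeline in one call: simulate, measure, analyse, report.

Equivalent to `ohf-engage report --seed 17 --out study_out/` from a shell.
"""

import tempfile

from ohf_engage import RunConfig, SimulationConfig, run_study

with tempfile.TemporaryDirectory() as out_dir:
    cfg = RunConfig(
        simulation=SimulationConfig(horizon_days=300),
        seed=17,
        out_dir=out_dir,
    )
    report = run_study(cfg)

    print(f"posts: {report.n_posts}, users: {report.n_users}, "
          f"threads: {report.n_threads}")
    print(f"total engagement value: {report.total_value:.0f}")
    for name, res in report.granger.items():
        fwd, rev = res["forward"], res["reverse"]
        print(f"{name}: {fwd['cause']}->{fwd['effect']} p={fwd['p']:.3g} | "
              f"{rev['cause']}->{rev['effect']} p={rev['p']:.3g}")
    if report.retention_curve and report.retention_curve["fit"]:
        f = report.retention_curve["fit"]
        print(f"retention curve fit: slope {f['slope']:.3f}, "
              f"adjusted R2 {f['adjusted_r2']:.2f}")
    print(f"(artefacts written to {out_dir}: capacity.csv, granger.json, "
          "propensity_*.csv, report.md)")
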