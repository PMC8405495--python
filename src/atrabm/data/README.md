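# Packaged fixtures

`synthetic_invitro_monolayer.csv` is a SYNTHETIC stand-in reference table:
smooth saturating γH2AX curves and dose-suppressed growth curves of the
shape and magnitude such monolayer drug-response assays produce.  It exists
so that the fixture-comparison machinery (`load_fixture`,
`rmse_against_fixture`, the `compare` CLI subcommand) can be exercised and
demonstrated end to end.  It is NOT measured data: RMSE values computed
against it say nothing about fit quality to any experiment.  To compare
against real measurements, supply your own CSV with columns
`source,dose,time_h,metric,mean,dispersion` (per-dose strictly increasing
times; `dispersion` is an s.d. or s.e. as your data defines it) and a
`source` value other than `synthetic`.
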