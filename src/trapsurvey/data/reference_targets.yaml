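# Reference values for the bundled standard designs, used only by the
# paper-run manifest's self-audit (computed-vs-reference pass/fail flags).
# Tolerances on Monte-Carlo quantities reflect desk-scale replication
# (200 iterations); closed-form and cost quantities are near-exact.
leek_standard_p:            {value: 0.86,    tolerance: 0.03}
leek_core_solitary_p:       {value: 0.85,    tolerance: 0.03}
leek_circle48_9.7_p:        {value: 0.73,    tolerance: 0.03}
medfly_standard_p:          {value: 0.71,    tolerance: 0.03}
medfly_core_solitary_p:     {value: 0.67,    tolerance: 0.03}
medfly_band2_solitary_p:    {value: 0.09,    tolerance: 0.03}
medfly_uniform_p:           {value: 0.74,    tolerance: 0.03}
medfly_alt3_p:              {value: 0.66,    tolerance: 0.03}
leek_moth_containment_p:    {value: 0.0,     tolerance: 0.01}
medfly_containment_p:       {value: 0.0,     tolerance: 0.01}
leek_moth_sigma_30d_m:      {value: 489.9,   tolerance: 1.0}
medfly_sigma_30d_m:         {value: 1549.2,  tolerance: 1.0}
leek_moth_p95_30d_m:        {value: 806.0,   tolerance: 1.0}
medfly_p95_30d_m:           {value: 2548.0,  tolerance: 2.0}
leek_moth_days_to_p95:      {value: 739.0,   tolerance: 1.0}
leek_standard_cost_usd:     {value: 25200.0, tolerance: 0.5}
medfly_standard_cost_usd:   {value: 44200.0, tolerance: 0.5}
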