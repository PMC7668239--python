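# Default exposure scenario for the brass-foundry study.
# avg_skin_dose is the unrounded mean of the 42 measured skin doses
# (reported rounded as 6.5 ug cm-2); all other values are the published
# scenario parameters.
avg_skin_dose: 6.557619047619048   # ug cm-2 accumulated over 2 h
hand_area: 1070.0                  # cm2, both hands
contact_area: 13.4                 # cm2, peri-oral contact surface
skin_absorption_2h: 0.00197        # dimensionless fraction
skin_absorption_24h: 0.00374       # dimensionless fraction
contact_frequency: 2.0             # hand-to-mouth events per hour
shift_hours: 8.0
transfer_efficiency: 0.24          # hand-to-saliva transfer per contact
gi_absorption: 0.20                # gastrointestinal absorption fraction
air_concentration: 1.2             # ug m-3, mean inhalable-PM Pb
inhaled_volume: 10.0               # m3 per 8-h shift
lung_absorption: 0.70
bksf: 0.4                          # ug dl-1 per ug day-1
workdays: 220.0                    # exposure days per year
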