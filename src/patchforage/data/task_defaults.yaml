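# Default task parameters (overridable copies for sensitivity analyses).
rich_sequence: [8, 7, 6, 5, 4]
poor_sequence: [5, 4, 3, 2, 1]
long_battery_s: 50.0
short_battery_s: 25.0
n_areas: 4
first_move_cost: t1
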