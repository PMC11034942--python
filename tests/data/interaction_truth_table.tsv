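case	di_lo	di_hi	a	a_sig	b	b_sig	ab	ab_sig	expected	audit
additive_pos_singles	-0.5	0.4	0.8	1	0.6	1	1.4	1	additive	0
additive_neg_singles	-0.5	0.4	-0.8	1	-0.6	1	-2.0	1	additive	0
additive_boundary_hi	-0.1	0.0	0.8	1	-0.6	1	0.1	0	additive	0
additive_boundary_lo	0.0	0.3	-0.8	0	0.6	0	0.0	0	additive	0
syn_neg_neg	-0.8	-0.2	-0.8	1	-0.6	1	-2.0	1	synergistic	0
syn_opp_pos_neg	-0.8	-0.2	0.8	1	-0.6	1	-0.3	1	synergistic	0
syn_opp_neg_pos	-0.8	-0.2	-0.8	1	0.6	0	0.3	0	synergistic	0
syn_pos_pos	0.2	0.8	0.8	1	0.6	1	2.0	1	synergistic	0
ant_hi_strong	-0.8	-0.2	0.8	1	0.6	1	0.3	1	strong_antagonistic	0
ant_hi_weak	-0.8	-0.2	0.8	1	0.6	1	0.9	1	weak_antagonistic	0
ant_hi_beyond_sum	-0.8	-0.2	0.8	1	0.6	1	1.5	1	strong_antagonistic	1
ant_hi_neutral	-0.8	-0.2	0.8	1	0.6	1	0.05	0	neutralizing	0
ant_hi_neutral_precedence	-0.8	-0.2	0.8	1	0.6	1	0.9	0	neutralizing	0
ant_hi_nosig_weakband	-0.8	-0.2	0.8	0	0.6	0	0.9	0	weak_antagonistic	0
ant_hi_nosig_nofit	-0.8	-0.2	0.8	0	0.6	0	0.05	0	strong_antagonistic	1
ant_hi_tie_min	-0.8	-0.2	0.8	1	0.6	1	0.6	1	weak_antagonistic	0
ant_hi_at_sum	-0.8	-0.2	0.8	1	0.6	1	1.4	1	strong_antagonistic	1
ant_lo_strong	0.2	0.8	-0.8	1	-0.6	1	-0.3	1	strong_antagonistic	0
ant_lo_weak	0.2	0.8	-0.8	1	-0.6	1	-0.9	1	weak_antagonistic	0
ant_lo_neutral	0.2	0.8	-0.8	1	-0.6	1	-0.05	0	neutralizing	0
ant_lo_beyond_sum	0.2	0.8	-0.8	1	-0.6	1	-2.0	1	strong_antagonistic	1
ant_lo_neutral_one_sig	0.2	0.8	-0.8	0	-0.6	1	-0.05	0	neutralizing	0
ant_lo_weak_flipped_sign	0.2	0.8	-0.8	1	-0.6	1	0.9	1	weak_antagonistic	0
ant_opp_strong	0.2	0.8	0.8	1	-0.6	1	0.3	1	strong_antagonistic	0
ant_opp_neutral	0.2	0.8	0.8	1	-0.6	1	0.1	0	neutralizing	0
ant_opp_nofit	0.2	0.8	0.8	1	-0.6	1	0.7	1	strong_antagonistic	1
ant_opp_neg_pos_strong	0.2	0.8	-0.8	1	0.6	1	-0.3	1	strong_antagonistic	0
ant_opp_nothing_sig	0.2	0.8	0.8	0	-0.6	0	0.1	0	strong_antagonistic	1
ant_opp_small_sig	0.2	0.8	0.8	1	-0.6	1	0.15	1	strong_antagonistic	0
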