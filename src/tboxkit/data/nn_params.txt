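# Simplified nearest-neighbor free-energy parameters (kcal/mol, 37 C).
# Watson-Crick stack values follow the standard Turner-style table; G:U
# stacks and loop-penalty curves are simplified bundled defaults.
#
# stack <outer pair> <inner pair> <dG>
#   outer pair (a,b) = bases at (i, j); inner pair (c,d) = bases at (i+1, j-1).
#   The loader symmetrizes: stack[(o,i)] == stack[(rev(i), rev(o))].
stack AU AU -0.93
stack AU UA -1.10
stack AU CG -2.24
stack AU GC -2.08
stack UA AU -1.33
stack UA CG -2.35
stack UA GC -2.11
stack CG CG -3.26
stack CG GC -2.36
stack GC CG -3.42
stack AU GU -0.55
stack AU UG -1.36
stack UA GU -1.27
stack UA UG -1.00
stack CG GU -1.41
stack CG UG -2.11
stack GC GU -1.53
stack GC UG -2.51
stack GU GU 0.47
stack GU UG -0.50
stack UG GU 1.29
#
# loop initiation penalties by size (unpaired bases); sizes beyond the table
# extrapolate as table_max + 1.75 * RT * ln(n / n_max), RT = 0.616.
hairpin 3 5.4
hairpin 4 5.6
hairpin 5 5.7
hairpin 6 5.4
hairpin 7 6.0
hairpin 8 5.5
hairpin 9 6.4
bulge 1 3.8
bulge 2 2.8
bulge 3 3.2
bulge 4 3.6
bulge 5 4.0
bulge 6 4.4
internal 2 1.7
internal 3 1.8
internal 4 1.1
internal 5 2.0
internal 6 2.3
#
# scalar terms
au_end 0.5
multiloop_init 3.4
multiloop_branch 0.4
multiloop_unpaired 0.0
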