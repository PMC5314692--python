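# Star-tier interaction counts for two successive releases (v1, v2) of a
# large integrated human interactome compendium, as printed in its release
# comparison table, together with the printed integer-percent increase
# ratios. Used only for internal arithmetic-consistency checks.
tier	v1_count	v2_count	printed_increase_pct
all	604741	2922202	483
5	37754	175476	464
4	33733	167123	495
3	71036	298149	419
2	189150	854189	452
1	273068	1427265	523
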