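name	category	trend_model_vs_control	trend_pa_vs_model
PC 32:1|PC 16:0_16:1	Glycerophospholipid	up	down
PC 32:2|PC 14:0_18:2	Glycerophospholipid	up	down
PC 33:1	Glycerophospholipid	up	down
PC 34:3|PC 16:1_18:2	Glycerophospholipid	up	down
PC 35:3	Glycerophospholipid	up	down
PC 36:4|PC 18:2_18:2	Glycerophospholipid	up	down
PC 38:6|PC 16:0_22:6	Glycerophospholipid	down	up
PC 40:6|PC 18:0_22:6	Glycerophospholipid	down	up
LPC 18:1_sn1	Glycerophospholipid	up	down
LPC 18:2_sn1	Glycerophospholipid	up	down
LPC 20:2_sn2	Glycerophospholipid	up	down
LPC 20:3_sn1	Glycerophospholipid	up	down
LPE 18:0_sn1	Glycerophospholipid	up	down
LPE 18:1_sn1	Glycerophospholipid	up	down
LPE 18:2_sn1	Glycerophospholipid	up	down
PE 38:4|PE 18:0_20:4	Glycerophospholipid	down	up
LPA 18:3_sn1	Glycerophospholipid	up	down
LPA 20:2_sn2	Glycerophospholipid	up	down
LNAPE 18:2/N-18:1	Glycerophospholipid	up	down
LNAPE 18:2/N-20:2	Glycerophospholipid	up	down
3-hydroxy-2-ethylpropionate	Leucine, Isoleucine, and Valine Metabolism	down	up
3-Hydroxyisovaleric Acid	Leucine, Isoleucine, and Valine Metabolism	down	up
3-Hydroxyisovalerylcarnitine	Leucine, Isoleucine, and Valine Metabolism	down	up
3-Methyl-2-Oxobutyrate	Leucine, Isoleucine, and Valine Metabolism	down	up
Isovalerylcarnitine (C5)	Leucine, Isoleucine, and Valine Metabolism	down	up
L-Isoleucine	Leucine, Isoleucine, and Valine Metabolism	down	up
L-Leucine	Leucine, Isoleucine, and Valine Metabolism	down	up
L-Valine	Leucine, Isoleucine, and Valine Metabolism	down	up
2-Methylpyrrolidine	Natural Product/Food/Plant	down	up
Epigallocatechin	Natural Product/Food/Plant	down	up
Ergothioneine	Natural Product/Food/Plant	down	up
Lumichrome	Natural Product/Food/Plant	down	up
N-Fructosyl isoleucine	Natural Product/Food/Plant	down	up
Oroxylin A-7-O-glucuronide	Natural Product/Food/Plant	up	down
Piperidine	Natural Product/Food/Plant	down	up
Pyrrolidine	Natural Product/Food/Plant	down	up
β-Muricholic Acid	Bile Acid	up	down
Hyocholic Acid	Bile Acid	up	down
Murocholic Acid	Bile Acid	up	down
Glycochenodeoxycholate Sulfate	Bile Acid, sulfated	up	down
FA 18:2+2O	Fatty Acid Metabolism	up	down
Carnitine	Fatty Acid Metabolism	down	up
L-Acetylcarnitine	Fatty Acid Metabolism	down	up
SM 32:2;O2	Sphingolipid Metabolism	up	down
SM 34:2;O2|SM 18:2;O2/16:0	Sphingolipid Metabolism	up	down
4-Cholesten-3-One	Sterol	up	down
7-Oxocholesterol	Sterol	up	down
5-hydroxylysine	Lysine Metabolism	down	up
L-Lysine	Lysine Metabolism	down	up
Guanidinosuccinic Acid	Urea cycle; Arginine and Proline Metabolism	down	up
N-Methylproline	Urea cycle; Arginine and Proline Metabolism	down	up
L-Allothreonine	Other Amino Acid Metabolism	down	up
L-Norvaline	Other Amino Acid Metabolism	down	up
N-Acetylhistidine	Histidine Metabolism	down	up
Octanoic Acid (C8:0)	Medium Chain Fatty Acid	down	up
Gamma-Tocopherol/Beta-Tocopherol	Tocopherol Metabolism	up	down
Pyridoxamine	Vitamin B6 Metabolism	down	up
Hexadecanedioate (C16-DC)	Fatty Acid, Dicarboxylate	up	down
2-HYDROXYOCTANOIC ACID	Fatty Acid, Monohydroxy	up	down
Glutathione Disulfide (GSSG)	Glutathione Metabolism	down	up
Xanthosine	Purine Metabolism, (Hypo)Xanthine/Inosine containing	down	up
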