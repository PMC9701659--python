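name	formula	kegg_id	source
L-Phenylalanine	C9H11NO2	C00079	KEGG
Caffeic acid	C9H8O4	C01197	KEGG
Sinapinic acid	C11H12O5	C00482	KEGG
p-Coumaroyl-shikimate	C16H16O7	C02947	KEGG
p-Coumaroyl quinic acid	C16H18O8	C12208	KEGG
Caffeoyl shikimic acid	C16H16O8	C10434	KEGG
p-Coumaraldehyde	C9H8O2	C05608	KEGG
Caffeyl alcohol	C9H10O3	C12206	KEGG
Caffeoylquinic acid	C16H18O9	C00852	KEGG
Ferulic acid	C10H10O4	C01494	KEGG
5-Hydroxyconiferaldehyde	C10H10O4	C12204	KEGG
Brassinolide	C28H48O6	C08814	KEGG
Castasterone	C28H48O5	C15794	KEGG
7-Oxateasterone	C28H48O5	C17733	KEGG
7-Oxatyphasterol	C28H48O5	C17735	KEGG
3-Dehydroteasterone	C28H46O4	C15792	KEGG
Homoeriodictyol chalcone	C16H14O6	C16405	KEGG
Sinapoyl malate	C15H16O9	C02887	KEGG
Coniferin	C16H22O8	C00761	KEGG
Syringin	C17H24O9	C01533	KEGG
Sinapaldehyde	C11H12O4	C05610	KEGG
2-Coumarinate	C9H8O3	C05838	KEGG
Caffeic aldehyde	C9H8O3	C10945	KEGG
Coniferyl aldehyde	C10H10O3	C02666	KEGG
p-Coumaric acid	C9H8O3	C00811	KEGG
beta-D-Glucosyl-2-coumarate	C15H18O8	C05839	KEGG
1-O-Sinapoyl-beta-D-glucose	C17H22O10	C01175	KEGG
N1,N5,N10-Triferuloyl spermidine	C37H43N3O9	C18071	KEGG
(22R,23R)-22,23-Dihydroxy-campest-4-en-3-one	C28H46O3	C16253	KEGG
6-Deoxoteasterone	C28H50O3	C15799	KEGG
6-Deoxotyphasterol	C28H50O3	C15801	KEGG
Teasterone	C28H48O4	C15791	KEGG
Typhasterol	C28H48O4	C15793	KEGG
3-Dehydro-6-deoxoteasterone	C28H48O3	C15800	KEGG
6-Deoxocastasterone	C28H50O4	C15802	KEGG
6alpha-Hydroxy-castasterone	C28H50O5	C15803	KEGG
Cathasterone	C28H48O3	C15790	KEGG
(22R,23R)-22,23-Dihydroxycampesterol	C28H48O3	C16252	KEGG
(-)-Epicatechin	C15H14O6	C09727	KEGG
Isoliquiritigenin	C15H12O4	C08650	KEGG
Liquiritigenin	C15H12O4	C09762	KEGG
Pinocembrin	C15H12O4	C09827	KEGG
2-(3'-Methylthio)propylmalic acid	C8H14O5S	C17214	KEGG
3-(3'-Methylthio)propylmalic acid	C8H14O5S	C17215	KEGG
2-(4'-Methylthio)butylmalic acid	C9H16O5S	C17218	KEGG
3-(4'-Methylthio)butylmalic acid	C9H16O5S	C17219	KEGG
2-Oxo-7-methylthioheptanoic acid	C8H14O3S	C17220	KEGG
3-(6'-Methylthio)hexylmalic acid	C11H20O5S	C17227	KEGG
2-(7'-Methylthio)heptylmalic acid	C12H22O5S	C17230	KEGG
3-(7'-Methylthio)heptylmalic acid	C12H22O5S	C17231	KEGG
S-(4-Methylthiobutylthiohydroximoyl)-L-cysteine	C8H16N2O3S2	C17242	KEGG
(E)-Phenylacetaldoxime	C8H9NO	C19714	KEGG
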