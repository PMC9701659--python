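map00940	Phenylpropanoid biosynthesis	C00079	C01197	C00482	C02947	C12208	C10434	C05608	C12206	C00852	C01494	C12204	C02887	C00761	C01533	C05610	C05838	C10945	C02666	C00811	C05839	C01175	C18071
map00905	Brassinosteroid biosynthesis	C08814	C15794	C17733	C17735	C15792	C16253	C15799	C15801	C15791	C15793	C15800	C15802	C15803	C15790	C16252
map00941	Flavonoid biosynthesis	C00852	C02947	C12208	C16405	C10434	C09727	C08650	C09762	C09827
map00966	Glucosinolate biosynthesis	C17214	C17215	C17218	C17219	C17220	C17227	C17230	C17231	C17242	C19714
map00945	Stilbenoid, diarylheptanoid and gingerol biosynthesis	C00852	C02947	C12208	C10434
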