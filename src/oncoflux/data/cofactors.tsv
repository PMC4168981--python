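cofactor_id	name	formula
nad_ox	NAD (oxidised)	C21H27N7O14P2
nad_red	NAD (reduced)	C21H29N7O14P2
h2o	water	H2O
co2	carbon dioxide	CO2
nh3	ammonia	H3N
atp	ATP	C10H16N5O13P3
adp	ADP	C10H15N5O10P2
sam	S-adenosylmethionine	C15H22N6O5S
sah	S-adenosylhomocysteine	C14H20N6O5S
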