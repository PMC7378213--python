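soil
sediment
watershed
rainfall
precipitation
drought
irrigation
aquifer
groundwater
salinity
erosion
topography
elevation
altitude
latitude
longitude
climate
seasonal
monsoon
temperate
tropical
boreal
tundra
savanna
grassland
wetland
estuary
lagoon
coastal
offshore
benthic
pelagic
plankton
phytoplankton
zooplankton
algae
kelp
coral
reef
mangrove
seagrass
fishery
fisheries
aquaculture
stocking
harvest
yield
forage
grazing
livestock
herbivore
predator
prey
carnivore
omnivore
foraging
migration
migratory
nesting
breeding-season
fledgling
plumage
antler
burrow
den
habitat
habitats
biome
biodiversity
richness
evenness
abundance
occupancy
transect
quadrat
survey
surveys
census
telemetry
tagging
banding
radar
satellite
remote-sensing
imagery
vegetation
canopy
understory
deciduous
coniferous
hardwood
sapling
seedling
germination
pollination
pollinator
nectar
blossom
orchard
vineyard
crop
crops
tillage
fertilizer
compost
mulch
pesticide
herbicide
weed
weeds
pasture
silage
granary
milling
brewing
fermentation-vat
distillation
viscosity
turbidity
sediments
limestone
granite
basalt
quartz
mineralogy
geology
tectonic
volcanic
magma
lava
seismic
earthquake
fault-line
glacier
glacial
moraine
permafrost
icecap
snowpack
avalanche
blizzard
hurricane
typhoon
cyclone
tornado
thunderstorm
lightning
humidity
barometric
windspeed
gust
breeze
tide
tides
tidal
current
currents
buoy
mooring
vessel
hull
keel
rudder
anchor
harbor
port
dock
cargo
freight
logistics
warehouse
inventory
retail
wholesale
commerce
tariff
export
import
currency
inflation
budget
auditing
ledger
payroll
staffing
recruitment
tourism
heritage
museum
archive
folklore
artisan
ceramic
textile
weaving
pottery
sculpture
mural
festival
parade
orchestra
melody
rhythm
chorus
lyric
theater
stagecraft
costume
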